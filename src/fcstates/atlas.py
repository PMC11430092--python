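"""Parcel-to-network labeling (Schaefer-style 100-parcel, 7-network atlas)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_NETWORKS = ("VIN", "SMN", "DAN", "VAN", "LIN", "FPN", "DMN")

__all__ = ["ParcelAtlas", "DEFAULT_NETWORKS", "default_atlas"]


@dataclass
class ParcelAtlas:
    """Assignment of each cortical parcel to exactly one network.

    ``network_labels`` holds one label per parcel, drawn from
    ``network_names``; each network must contain at least two parcels
    so within-network mean connectivity is defined.
    """

    network_labels: list[str]
    network_names: tuple[str, ...] = DEFAULT_NETWORKS

    def __post_init__(self) -> None:
        if set(self.network_labels) != set(self.network_names):
            raise ValueError("label set must equal network_names")
        counts = pd.Series(self.network_labels).value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"networks with < 2 parcels: {small}")

    @property
    def n_parcels(self) -> int:
        return len(self.network_labels)

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    def indices(self, network: str) -> np.ndarray:
        """Parcel indices belonging to ``network``."""
        return np.flatnonzero(np.asarray(self.network_labels) == network)

    def label_codes(self) -> np.ndarray:
        """Per-parcel integer code into ``network_names``."""
        lookup = {name: i for i, name in enumerate(self.network_names)}
        return np.array([lookup[l] for l in self.network_labels])

    def network_pairs(self) -> list[tuple[str, str]]:
        """The unordered distinct network pairs, in canonical order."""
        names = self.network_names
        return [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"parcel_id": range(self.n_parcels), "network": self.network_labels}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, network_names=DEFAULT_NETWORKS) -> "ParcelAtlas":
        df = pd.read_csv(path).sort_values("parcel_id")
        return cls(df["network"].tolist(), tuple(network_names))


def default_atlas(n_parcels: int = 100, network_names=DEFAULT_NETWORKS) -> ParcelAtlas:
    """Contiguous near-equal split of ``n_parcels`` over the 7 networks."""
    n_net = len(network_names)
    base, extra = divmod(n_parcels, n_net)
    sizes = [base + (1 if i < extra else 0) for i in range(n_net)]
    labels: list[str] = []
    for name, size in zip(network_names, sizes):
        labels.extend([name] * size)
    return ParcelAtlas(labels, tuple(network_names))
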