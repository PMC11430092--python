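"""End-to-end orchestration: simulate -> envelope -> HMM -> features ->
backbone -> statistics -> report.

All stage boundaries are plain CSV/JSON files inside one artifact
directory so any stage can be rerun or inspected in isolation; a
manifest records the configuration, seeds, and content hashes of every
stage output, making a rerun with the same config byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import envelope as env_mod
from . import hmm as hmm_mod
from . import spatial, temporal
from .atlas import ParcelAtlas, default_atlas
from .backbone import (
    AlphaSearch,
    WeightedGraphSet,
    aggregate_edges,
    apply_backbone,
    bootstrap_median,
    optimize_alpha,
)
from .simulate import CohortSpec, SubjectRecording, default_ground_truth, generate_cohort
from .stats import compare_groups

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "render_report",
           "default_families", "subject_feature_table"]


@dataclass
class PipelineConfig:
    """Declarative parameters of the full analysis.

    Defaults follow the reference analysis: 250 Hz working rate, PCA
    retaining 95% variance, candidate state counts 3..12, 10,000
    bootstrap iterations, and a disparity-filter alpha searched over
    [0.001, 0.10].
    """

    # cohort simulation
    groups: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {"YAC": (15, 1.15), "OAC": (15, 1.0), "TCOA": (15, 1.3)}
    )
    duration_s: float = 60.0
    fs: float = 250.0
    master_seed: int = 0
    # envelope stage
    fs_target: float = 250.0
    orthogonalize: bool = True
    orthogonalization_method: str = "qr"
    # state model
    pca_retained: float = 0.95
    pca_max_dim: int | None = 20
    K_range: tuple[int, int] = (3, 12)
    K_fixed: int | None = None  # skip selection when set
    em_max_iter: int = 30
    em_tol_per_sample: float = 3.3e-4
    n_restarts: int = 1
    selection_subjects: int | None = None  # cap subjects entering selection
    # spatial features
    min_window: int = 25
    # backbone
    backbone_enabled: bool = True
    n_iter_bootstrap: int = 10_000
    alpha_start: float = 0.001
    alpha_end: float = 0.10
    # statistics
    comparisons: tuple[tuple[str, str], ...] = (("OAC", "YAC"), ("OAC", "TCOA"))
    p_method: str = "asymptotic"

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["groups"] = {k: list(v) for k, v in self.groups.items()}
        payload["K_range"] = list(self.K_range)
        payload["comparisons"] = [list(c) for c in self.comparisons]
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["groups"] = {k: tuple(v) for k, v in raw["groups"].items()}
        raw["K_range"] = tuple(raw["K_range"])
        raw["comparisons"] = tuple(tuple(c) for c in raw["comparisons"])
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    atlas: ParcelAtlas
    K_star: int
    feature_table: pd.DataFrame
    comparisons: dict[tuple[str, str], pd.DataFrame]
    group_fc: dict[str, np.ndarray]
    manifest: dict


def default_families(atlas: ParcelAtlas) -> dict[str, str]:
    """FDR families: within-network, between-network, each temporal type."""
    fam = {}
    for net in atlas.network_names:
        fam[f"within_{net}"] = "within_network"
    for a, b in atlas.network_pairs():
        fam[f"between_{a}_{b}"] = "between_network"
    return fam


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def subject_feature_table(
    rows: list[dict],
) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["subject_id", "group", "feature", "value"])


def _envelope_stage(
    rec: SubjectRecording, cfg: PipelineConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject envelopes for state modelling and for connectivity.

    Returns (raw envelope matrix, connectivity matrix).  The state
    model consumes raw (strictly positive) envelopes; connectivity
    uses the orthogonalized envelopes when enabled.
    """
    series, fs = env_mod.downsample(rec.parcel_series, rec.fs, cfg.fs_target)
    env = env_mod.EnvelopeMatrix(np.abs(series), fs) if (series >= 0).all() else None
    if env is None:
        env = env_mod.hilbert_envelope(series, fs)
    if cfg.orthogonalize:
        conn, _ = env_mod.orthogonalize(env, cfg.orthogonalization_method)
    else:
        conn = env.values
    return env.values, conn


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    recordings: list[SubjectRecording] | None = None,
    atlas: ParcelAtlas | None = None,
) -> PipelineResult:
    """Run every stage on a simulated (or supplied) cohort."""
    atlas = atlas or default_atlas()
    if recordings is None:
        spec = CohortSpec(
            atlas=atlas,
            model=default_ground_truth(atlas),
            groups=config.groups,
            duration_s=config.duration_s,
            fs=config.fs,
            master_seed=config.master_seed,
        )
        recordings = generate_cohort(spec)

    hmm_cfg = hmm_mod.HMMConfig(
        K_range=config.K_range,
        pca_retained=config.pca_retained,
        pca_max_dim=config.pca_max_dim,
        em_max_iter=config.em_max_iter,
        em_tol_per_sample=config.em_tol_per_sample,
        n_restarts=config.n_restarts,
        seed=config.master_seed,
    )

    envelopes, conn_mats = [], []
    for rec in recordings:
        e, c = _envelope_stage(rec, config)
        envelopes.append(e)
        conn_mats.append(c)

    # ---- state count ----
    if config.K_fixed is not None:
        K_star = config.K_fixed
        selection = None
    else:
        n_sel = config.selection_subjects or len(envelopes)
        selection = hmm_mod.select_n_states(
            [e.T for e in envelopes[:n_sel]], hmm_cfg
        )
        K_star = selection.K_star

    # ---- shared model on concatenated standardized data ----
    reduced, lengths = [], []
    pooled = []
    for e in envelopes:
        z = hmm_mod.preprocess_features(e.T, hmm_cfg)
        pooled.append(z)
        lengths.append(z.shape[0])
    pooled_mat = np.vstack(pooled)
    scores, pca, d = hmm_mod.pca_reduce(
        pooled_mat, config.pca_retained, config.pca_max_dim
    )
    model = hmm_mod.fit_hmm(scores, K_star, hmm_cfg, lengths=lengths)

    # ---- per-subject decode + features ----
    feature_rows: list[dict] = []
    state_fcs: dict[str, spatial.StateFC] = {}
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    backbone_log = None
    for idx, rec in enumerate(recordings):
        seq = hmm_mod.decode(
            model, scores[offsets[idx] : offsets[idx + 1]], config.fs_target
        )
        tf = temporal.temporal_features(seq, K_star)
        windows = spatial.segment_states(seq)
        fc = spatial.compute_state_fc(
            conn_mats[idx], windows, K_star, config.min_window
        )
        state_fcs[rec.subject_id] = fc
        summary = spatial.subject_connectivity(fc, tf.fractional_occupancy, atlas)
        per_state = [
            spatial.network_means(fc.matrices[k], atlas)
            if fc.support[k] > 0
            else None
            for k in range(K_star)
        ]
        try:
            tm = spatial.transition_magnitude(
                per_state, tf.transition_probs, tf.fractional_occupancy, atlas
            )
        except ValueError:
            tm = None
        base = {"subject_id": rec.subject_id, "group": rec.group}
        for net in atlas.network_names:
            feature_rows.append({**base, "feature": f"within_{net}", "value": summary.within[net]})
        for a, b in atlas.network_pairs():
            feature_rows.append({**base, "feature": f"between_{a}_{b}", "value": summary.between[(a, b)]})
        if tm is not None:
            for net in atlas.network_names:
                feature_rows.append({**base, "feature": f"tm_within_{net}", "value": tm.within[net]})
            for a, b in atlas.network_pairs():
                feature_rows.append({**base, "feature": f"tm_between_{a}_{b}", "value": tm.between[(a, b)]})
        for k in range(K_star):
            feature_rows.append({**base, "feature": f"fo_state{k}", "value": tf.fractional_occupancy[k]})
            feature_rows.append({**base, "feature": f"lifetime_state{k}", "value": tf.mean_lifetime_s[k]})
            feature_rows.append({**base, "feature": f"interval_state{k}", "value": tf.mean_interval_s[k]})

    # ---- backbone on per-subject mean state FC (windows = states) ----
    if config.backbone_enabled:
        group_names = sorted({r.group for r in recordings})
        mats = []
        for rec in recordings:
            fc = state_fcs[rec.subject_id]
            for k in range(K_star):
                if fc.support[k] > 0:
                    m = np.nan_to_num(fc.matrices[k].copy())
                    np.fill_diagonal(m, 0.0)
                    mats.append(m)
        graphs = WeightedGraphSet(np.stack(mats))
        pool = aggregate_edges(graphs)
        boot = bootstrap_median(pool, config.n_iter_bootstrap, config.master_seed)
        search = AlphaSearch(config.alpha_start, config.alpha_end)
        alpha_opt, alpha_log = optimize_alpha(graphs, boot.M, search)
        _, backbone_log = apply_backbone(graphs, boot.M, alpha_opt)
        backbone_log.update(alpha_log)
        backbone_log["n_windows"] = len(mats)

    feature_table = subject_feature_table(feature_rows)

    # ---- statistics ----
    fam = default_families(atlas)
    for f in feature_table["feature"].unique():
        if f.startswith("tm_within"):
            fam.setdefault(f, "tm_within")
        elif f.startswith("tm_between"):
            fam.setdefault(f, "tm_between")
        elif f.startswith("fo_"):
            fam.setdefault(f, "fractional_occupancy")
        elif f.startswith("lifetime_"):
            fam.setdefault(f, "lifetime")
        elif f.startswith("interval_"):
            fam.setdefault(f, "interval")
    comparisons = {}
    for pair in config.comparisons:
        comparisons[pair] = compare_groups(
            feature_table, pair, fam, method=config.p_method
        )

    # ---- group-average FC matrices (occupancy-weighted) ----
    group_fc: dict[str, np.ndarray] = {}
    for g in sorted({r.group for r in recordings}):
        accum = []
        for rec in recordings:
            if rec.group != g:
                continue
            fc = state_fcs[rec.subject_id]
            w = fc.support / fc.support.sum()
            mat = np.zeros_like(fc.matrices[0])
            for k in range(K_star):
                if fc.support[k] > 0:
                    mat += w[k] * np.nan_to_num(fc.matrices[k])
            accum.append(mat)
        group_fc[g] = np.mean(accum, axis=0)

    manifest = {
        "config": dataclasses.asdict(config),
        "n_subjects": len(recordings),
        "K_star": int(K_star),
        "pca_dim": int(d),
        "feature_hash": _hash(feature_table.round(12).to_dict("records")),
        "backbone": backbone_log,
    }
    result = PipelineResult(
        config=config,
        atlas=atlas,
        K_star=K_star,
        feature_table=feature_table,
        comparisons=comparisons,
        group_fc=group_fc,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.feature_table.to_csv(out_dir / "features.csv", index=False)
    for (g1, g2), df in result.comparisons.items():
        df.to_csv(out_dir / f"comparison_{g1}_vs_{g2}.csv", index=False)
    for g, mat in result.group_fc.items():
        np.savetxt(out_dir / f"group_fc_{g}.csv", mat, delimiter=",")
    result.config.to_yaml(out_dir / "config.yaml")
    (out_dir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=str)
    )


def render_report(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Comparison tables plus z-scored, network-ordered FC heatmaps."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for (g1, g2), df in result.comparisons.items():
        p = out_dir / f"table_{g1}_vs_{g2}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    atlas = result.atlas
    order = np.argsort(atlas.label_codes(), kind="stable")
    bounds = np.cumsum(
        [len(atlas.indices(n)) for n in atlas.network_names]
    )[:-1]
    for g, mat in result.group_fc.items():
        m = mat[np.ix_(order, order)].copy()
        off = ~np.eye(len(m), dtype=bool)
        mu, sd = m[off].mean(), m[off].std()
        z = (m - mu) / (sd if sd > 0 else 1.0)
        np.fill_diagonal(z, 0.0)
        fig, ax = plt.subplots(figsize=(6, 5))
        vmax = np.abs(z).max() or 1.0
        im = ax.imshow(z, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        for b in bounds:
            ax.axhline(b - 0.5, color="k", lw=0.4)
            ax.axvline(b - 0.5, color="k", lw=0.4)
        ticks = np.concatenate([[0], bounds])
        centers = (np.concatenate([ticks, [len(m)]])[:-1] + np.concatenate([ticks, [len(m)]])[1:]) / 2
        ax.set_xticks(centers, atlas.network_names, rotation=90, fontsize=7)
        ax.set_yticks(centers, atlas.network_names, fontsize=7)
        ax.set_title(f"{g}: z-scored state-weighted FC")
        fig.colorbar(im, ax=ax, shrink=0.8)
        p = out_dir / f"fc_matrix_{g}.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    return written
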