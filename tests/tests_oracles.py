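"""Brute-force oracle implementations shared across test modules.

Deliberately naive (explicit loops, no vectorization) so they stay
independent of the package's own computation paths.
"""

import numpy as np


def brute_occupancy(labels, K):
    return np.array([(labels == k).sum() for k in range(K)]) / len(labels)


def brute_lifetime(labels, K, fs):
    runs = []
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[t - 1]:
            runs.append((labels[start], t - start))
            start = t
    out = np.full(K, np.nan)
    for k in range(K):
        ls = [l for s, l in runs if s == k]
        if ls:
            out[k] = np.mean(ls) / fs
    return out


def brute_interval(labels, K, fs):
    out = np.full(K, np.nan)
    for k in range(K):
        visits = []
        start = None
        for t, v in enumerate(labels):
            if v == k and start is None:
                start = t
            elif v != k and start is not None:
                visits.append((start, t))
                start = None
        if start is not None:
            visits.append((start, len(labels)))
        if len(visits) >= 2:
            gaps = [visits[i + 1][0] - visits[i][1] for i in range(len(visits) - 1)]
            out[k] = np.mean(gaps) / fs
    return out


def brute_transitions(labels, K):
    counts = np.zeros((K, K))
    for a, b in zip(labels[:-1], labels[1:]):
        counts[a, b] += 1
    sums = counts.sum(1, keepdims=True)
    with np.errstate(invalid="ignore"):
        probs = counts / sums
    probs[sums[:, 0] == 0] = np.nan
    return probs


def step_up_oracle(p):
    """Direct Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        adj[order[rank - 1]] = running
    return adj
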