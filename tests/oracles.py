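"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's counting/vectorized formulations:
entropy is estimated by explicit pairwise window matching, fluctuation
values by per-segment polynomial fits, and metrics by direct arithmetic.
"""

from __future__ import annotations

import math

import numpy as np


def _pairwise_hamming(c: np.ndarray, m: int, tau: int) -> np.ndarray:
    """(n_win, n_win) Hamming distances between all embedded window pairs."""
    c = np.asarray(c, dtype=np.int64)
    n_win = c.size - (m - 1) * tau
    assert n_win >= 1
    wins = np.stack([c[i : i + (m - 1) * tau + 1 : tau] for i in range(n_win)])
    packed = wins @ (1 << np.arange(m, dtype=np.int64))
    return np.bitwise_count(packed[:, None] ^ packed[None, :])


def naive_phi(c: np.ndarray, m: int, r: int, tau: int = 1) -> float:
    """O(N^2) pairwise matching estimate of the log-average probability.

    Counts, for every window, the fraction of windows (self included)
    within Hamming distance r, and averages the log over windows.
    """
    dist = _pairwise_hamming(c, m, tau)
    p = (dist <= r).sum(axis=1) / dist.shape[0]
    return float(np.mean(np.log(p)))


def naive_binen(x: np.ndarray, m: int, r: int, tau: int = 1) -> float:
    """Pairwise-matching BinEn: sign-encode, then phi(m) - phi(m+1)."""
    x = np.asarray(x, dtype=float)
    c = (np.diff(x) > 0).astype(np.int64)
    return naive_phi(c, m, r, tau) - naive_phi(c, m + 1, r, tau)


def naive_binen_grid(x: np.ndarray, ms=(1, 2, 3, 4), tau: int = 1) -> dict:
    """Pairwise BinEn for every (m, r) pair, reusing distance matrices."""
    x = np.asarray(x, dtype=float)
    c = (np.diff(x) > 0).astype(np.int64)
    dists = {m: _pairwise_hamming(c, m, tau) for m in range(min(ms), max(ms) + 2)}

    def phi_from(dist, r):
        p = (dist <= r).sum(axis=1) / dist.shape[0]
        return float(np.mean(np.log(p)))

    return {
        (m, r): phi_from(dists[m], r) - phi_from(dists[m + 1], r)
        for m in ms
        for r in range(m + 1)
    }


def naive_segment_fd(profile: np.ndarray, sl: int) -> np.ndarray:
    """Per-segment mean squared residual via numpy.polyfit."""
    profile = np.asarray(profile, dtype=float)
    n_seg = profile.size // sl
    k = np.arange(sl, dtype=float)
    out = []
    for j in range(n_seg):
        seg = profile[j * sl : (j + 1) * sl]
        coef = np.polyfit(k, seg, 1)
        out.append(float(np.mean((seg - np.polyval(coef, k)) ** 2)))
    return np.asarray(out)


def naive_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Direct evaluation of the six measures; None where undefined."""

    def frac(a, b):
        return a / b if b else None

    sens = frac(tp, tp + fn)
    spec = frac(tn, tn + fp)
    ba = 100.0 * (sens + spec) / 2.0 if sens is not None and spec is not None else None
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tn * tp - fn * fp) / math.sqrt(den) if den else None
    return {
        "balanced_accuracy": ba,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": frac(tp, tp + fp),
        "npv": frac(tn, tn + fn),
        "mcc": mcc,
    }
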