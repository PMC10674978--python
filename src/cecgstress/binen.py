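"""Binarized approximate entropy (BinEn) of a numeric time series.

The series is reduced to the sign sequence of its first differences; the
entropy is then an approximate-entropy-style difference of two log-average
matching probabilities, computed in linear time by counting the 2**m
possible binary embedding vectors and comparing vector codes through a
precomputed Hamming-distance matrix instead of matching windows pairwise.

Only the signs of differences enter the computation, so the result is
invariant to any strictly increasing transform of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BinEnParams",
    "binary_diff_encode",
    "vector_decimal",
    "vector_counts",
    "hamming_matrix",
    "phi",
    "binen",
]


@dataclass(frozen=True)
class BinEnParams:
    """Embedding size ``m``, delay ``tau`` and Hamming tolerance ``r``.

    ``r = 0`` (exact match) is the default: for binary symbols it turns the
    estimate into a conditional-entropy rate. ``r`` must lie in ``0..m``.
    """

    m: int = 2
    tau: int = 1
    r: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if not 0 <= self.r <= self.m:
            raise ValueError(f"r must be in 0..m={self.m}, got {self.r}")


def binary_diff_encode(x: np.ndarray) -> np.ndarray:
    """Sign-of-difference encoding: ``c[i] = 1`` iff ``x[i+1] - x[i] > 0``.

    Ties (zero difference) encode to 0. Output length is ``len(x) - 1``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to difference-encode")
    return (np.diff(x) > 0).astype(np.uint8)


def vector_decimal(c_window: np.ndarray) -> int:
    """Decimal code of one binary embedding vector, first element = LSB."""
    c_window = np.asarray(c_window)
    m = c_window.size
    if m < 1:
        raise ValueError("empty window")
    if not np.all((c_window == 0) | (c_window == 1)):
        raise ValueError("window must be binary")
    return int(np.dot(c_window, 1 << np.arange(m)))


def _window_codes(c: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Decimal codes of all N - (m-1)*tau delay-embedded windows."""
    n_win = c.size - (m - 1) * tau
    if n_win < 1:
        raise ValueError(
            f"sequence of length {c.size} too short for m={m}, tau={tau}"
        )
    codes = np.zeros(n_win, dtype=np.int64)
    for n in range(m):
        codes += c[n * tau : n * tau + n_win].astype(np.int64) << n
    return codes


def vector_counts(c: np.ndarray, m: int, tau: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Occurrence counts and pmf of the 2**m binary embedding vectors.

    Returns ``(counts, pmf)`` where ``counts[k]`` is the number of windows
    whose decimal code is ``k`` and ``pmf = counts / n_windows``.
    """
    c = np.asarray(c)
    codes = _window_codes(c, m, tau)
    counts = np.bincount(codes, minlength=2**m).astype(np.int64)
    return counts, counts / codes.size


def hamming_matrix(m: int) -> np.ndarray:
    """(2**m, 2**m) matrix of Hamming distances between vector codes."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    k = np.arange(2**m)
    xor = np.bitwise_xor.outer(k, k)
    # popcount via uint8 bit-count lookup; m <= 62 in practice
    h = np.zeros_like(xor)
    while xor.any():
        h += xor & 1
        xor >>= 1
    return h


def phi(c: np.ndarray, m: int, r: int, tau: int = 1) -> float:
    """Log-average matching probability at embedding size ``m``.

    ``p_k`` is the probability that a random window lies within Hamming
    distance ``r`` of a window with code ``k``; the return value is the
    pmf-weighted average of ``ln p_k``, which is <= 0. Self-matches are
    included, so the logarithm is always defined.
    """
    if not 0 <= r <= m:
        raise ValueError(f"r must be in 0..m={m}, got {r}")
    _, pmf = vector_counts(c, m, tau)
    within = hamming_matrix(m) <= r
    p = within @ pmf
    occ = pmf > 0
    return float(np.dot(pmf[occ], np.log(p[occ])))


def binen(x: np.ndarray, params: BinEnParams = BinEnParams()) -> float:
    """Binarized approximate entropy of ``x`` in nats.

    Difference of the log-average matching probabilities at embedding
    sizes ``m`` and ``m + 1``. Requires ``len(x) >= m*tau + 2`` so that
    both orders have at least one window.
    """
    x = np.asarray(x, dtype=float)
    m, tau, r = params.m, params.tau, params.r
    if x.size < m * tau + 2:
        raise ValueError(
            f"need at least m*tau + 2 = {m * tau + 2} samples, got {x.size}"
        )
    c = binary_diff_encode(x)
    return phi(c, m, r, tau) - phi(c, m + 1, r, tau)
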