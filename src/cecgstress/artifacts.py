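"""Segment-wise elimination of coarse motion artifacts and slow drift.

The signal's centralized cumulative sum is split into non-overlapping
segments; the mean squared residual of a per-segment linear fit (the
detrended-fluctuation value, FD) measures how violently each segment
departs from its own trend. When a global range-vs-power check flags the
trace as contaminated, segments whose FD exceeds a data-driven threshold
TH1 are dropped, neighbours that differ by more than TH1/2 are dropped as
spill-over, and a fixed low threshold TH3 removes slow-drift segments when
the FD population sits above it. The denoised output is the concatenation
of the kept segments (the time axis is compressed, not interpolated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from cecgstress.signal import Signal

__all__ = [
    "PreprocParams",
    "SegmentationResult",
    "EliminationReason",
    "centralized_cumsum",
    "segment_fd",
    "coarse_present",
    "compute_th1",
    "reduce_artifacts",
]


class EliminationReason(str, Enum):
    KEPT = "kept"
    COARSE = "coarse"
    ADJACENT = "adjacent"
    SLOW = "slow"


@dataclass(frozen=True)
class PreprocParams:
    """Tuning constants of the elimination procedure.

    ``segment_length`` is in samples; ``None`` means one second of signal
    (fs samples), so a coarse transient dominates its segment. ``c`` must
    stay within [0.15, 0.35] (units 1/mV**2); ``c1`` is 1 mV; ``th3`` is
    the slow-drift threshold in mV**2. Only linear detrending
    (``poly_order = 1``) is supported.
    """

    segment_length: int | None = None
    c: float = 0.25
    c1: float = 1.0
    th3: float = 0.1
    poly_order: int = 1
    global_coarse_check: bool = True

    def __post_init__(self) -> None:
        if self.segment_length is not None and self.segment_length < 4:
            raise ValueError("segment_length must be >= 4 samples")
        if not 0.15 <= self.c <= 0.35:
            raise ValueError(f"c must lie in [0.15, 0.35], got {self.c}")
        if self.poly_order != 1:
            raise ValueError("only linear detrending (poly_order=1) is supported")

    def resolve_sl(self, fs: float) -> int:
        sl = int(round(fs)) if self.segment_length is None else self.segment_length
        if sl < 4:
            raise ValueError(f"resolved segment length {sl} < 4 samples")
        return sl


@dataclass
class SegmentationResult:
    """Per-segment bookkeeping of one elimination run."""

    fd: np.ndarray
    second_moment: float
    th1: float | None
    th2: float | None
    segment_length: int
    keep_mask: np.ndarray
    reasons: list[EliminationReason]
    kept_sample_index_map: np.ndarray
    coarse_detected: bool
    all_eliminated: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return self.fd.size

    @property
    def eliminated_fraction(self) -> float:
        return 1.0 - float(np.mean(self.keep_mask)) if self.fd.size else 0.0


def centralized_cumsum(x: np.ndarray | Signal) -> np.ndarray:
    """Cumulative sum of mean-subtracted samples; last element ~ 0."""
    samples = x.samples if isinstance(x, Signal) else np.asarray(x, dtype=float)
    if samples.size == 0:
        raise ValueError("empty input")
    return np.cumsum(samples - samples.mean())


def segment_fd(profile: np.ndarray, sl: int) -> np.ndarray:
    """Mean squared residual of a linear fit, per non-overlapping segment.

    The profile is cut into ``floor(N / sl)`` segments; a trailing
    remainder shorter than ``sl`` is ignored. Each segment is fit by
    least squares against the within-segment sample index.
    """
    profile = np.asarray(profile, dtype=float)
    if sl > profile.size:
        raise ValueError(f"segment length {sl} exceeds profile length {profile.size}")
    if sl < 2:
        raise ValueError("segment length must be >= 2 for a linear fit")
    n_seg = profile.size // sl
    seg = profile[: n_seg * sl].reshape(n_seg, sl)
    k = np.arange(sl, dtype=float)
    # closed-form simple linear regression, vectorized over segments
    k_mean = k.mean()
    k_var = np.mean((k - k_mean) ** 2)
    y_mean = seg.mean(axis=1)
    slope = np.mean((k - k_mean) * (seg - y_mean[:, None]), axis=1) / k_var
    resid = seg - (y_mean[:, None] + slope[:, None] * (k - k_mean))
    return np.mean(resid**2, axis=1)


def second_moment(x: np.ndarray) -> float:
    """Mean of squared samples (mV**2)."""
    x = np.asarray(x, dtype=float)
    return float(np.mean(x**2))


def coarse_present(x: np.ndarray | Signal) -> bool:
    """Global check for coarse artifacts: half-range minus signal power > 1.

    Amplitudes are in mV; the constant 1 is the documented mV convention.
    """
    samples = x.samples if isinstance(x, Signal) else np.asarray(x, dtype=float)
    half_range = (samples.max() - samples.min()) / 2.0
    return bool(half_range - second_moment(samples) > 1.0)


def compute_th1(
    x: np.ndarray | Signal, fd: np.ndarray, params: PreprocParams = PreprocParams()
) -> float:
    """Data-driven coarse-elimination threshold.

    ``TH1 = (half_range**2 - M) * C * (median(FD) + SD(FD) + SD(x))
    / (SD(FD) * SD(x) * C1)`` with population standard deviations.
    Degenerate inputs (constant signal or constant FD) raise.
    """
    samples = x.samples if isinstance(x, Signal) else np.asarray(x, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if fd.size < 2:
        raise ValueError("need at least 2 segments to form TH1")
    sd_fd = float(np.std(fd))
    sd_x = float(np.std(samples))
    if sd_fd == 0.0 or sd_x == 0.0:
        raise ValueError("degenerate input: zero standard deviation in FD or x")
    half_range = (samples.max() - samples.min()) / 2.0
    m2 = second_moment(samples)
    th1 = (
        (half_range**2 - m2)
        * params.c
        * (float(np.median(fd)) + sd_fd + sd_x)
        / (sd_fd * sd_x * params.c1)
    )
    if not np.isfinite(th1):
        raise ValueError("TH1 is not finite")
    return float(th1)


def reduce_artifacts(
    x: Signal, params: PreprocParams = PreprocParams()
) -> tuple[SegmentationResult, Signal]:
    """Run the full elimination procedure and return (result, denoised).

    When the coarse check is negative the signal passes through
    bit-identical (raw and denoised overlap perfectly). Otherwise the
    denoised signal is the concatenation of kept whole segments, so its
    length is ``segment_length * n_kept``; a trailing remainder shorter
    than one segment is discarded on this path. If everything is
    eliminated the result is flagged, not raised.
    """
    sl = params.resolve_sl(x.fs)
    n = len(x)
    if n < 2 * sl:
        raise ValueError(f"signal of {n} samples too short for 2 segments of {sl}")

    profile = centralized_cumsum(x)
    fd = segment_fd(profile, sl)
    n_seg = fd.size
    m2 = second_moment(x.samples)
    coarse = coarse_present(x) if params.global_coarse_check else True

    if not coarse:
        result = SegmentationResult(
            fd=fd,
            second_moment=m2,
            th1=None,
            th2=None,
            segment_length=sl,
            keep_mask=np.ones(n_seg, dtype=bool),
            reasons=[EliminationReason.KEPT] * n_seg,
            kept_sample_index_map=np.arange(n),
            coarse_detected=False,
        )
        return result, Signal(x.samples.copy(), x.fs, dict(x.meta, denoised=True))

    th1 = compute_th1(x, fd, params)
    th2 = th1 / 2.0
    reasons = [EliminationReason.KEPT] * n_seg
    keep = np.ones(n_seg, dtype=bool)

    candidates = np.flatnonzero(fd > th1)
    for j in candidates:
        keep[j] = False
        reasons[j] = EliminationReason.COARSE
    # spill-over: a neighbour of an eliminated candidate goes too when its
    # FD differs from the candidate's by more than TH2
    for j in candidates:
        for nb in (j - 1, j + 1):
            if 0 <= nb < n_seg and keep[nb] and abs(fd[j] - fd[nb]) > th2:
                keep[nb] = False
                reasons[nb] = EliminationReason.ADJACENT

    # slow-drift pass, active only when the FD population sits high
    if float(np.mean(fd)) - float(np.std(fd)) > params.th3:
        for j in np.flatnonzero(fd > params.th3):
            if keep[j]:
                keep[j] = False
                reasons[j] = EliminationReason.SLOW

    kept_idx = np.concatenate(
        [np.arange(j * sl, (j + 1) * sl) for j in np.flatnonzero(keep)]
    ) if keep.any() else np.array([], dtype=int)

    result = SegmentationResult(
        fd=fd,
        second_moment=m2,
        th1=th1,
        th2=th2,
        segment_length=sl,
        keep_mask=keep,
        reasons=reasons,
        kept_sample_index_map=kept_idx,
        coarse_detected=True,
        all_eliminated=not keep.any(),
    )
    denoised = Signal(
        x.samples[kept_idx].copy(), x.fs, dict(x.meta, denoised=True)
    )
    return result, denoised
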