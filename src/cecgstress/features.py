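"""R-peak detection and per-window features: R value, HR, pNNx, BinEn.

The detector is a small Pan–Tompkins-family pipeline (bandpass,
differentiate, square, moving-window integrate, adaptive threshold) with
the final peak position refined to the local maximum of the raw trace, so
reported amplitudes are raw-sample values. Everything downstream needs
only these R positions: instantaneous heart rate, the fraction of
successive-interval differences above a threshold (pNNx), and the
binarized approximate entropy of the window's samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from cecgstress.binen import BinEnParams, binen
from cecgstress.signal import Signal

__all__ = [
    "RPeakSeries",
    "FeatureVector",
    "detect_rpeaks",
    "heart_rate",
    "pnnx",
    "window_features",
]

MIN_RRI_MS = 250.0  # anything faster than 240 bpm is rejected as implausible


@dataclass
class RPeakSeries:
    """Detected R peaks: sample indices, raw amplitudes, RR intervals (ms)."""

    indices: np.ndarray
    amplitudes: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size

    @property
    def rri_ms(self) -> np.ndarray:
        return np.diff(self.indices) / self.fs * 1000.0


@dataclass
class FeatureVector:
    """The four features of one window plus its label and provenance."""

    r_value: float
    hr: float
    pnn50: float
    binen: float
    label: str | None = None
    subject: str | None = None
    window_index: int = 0
    meta: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "subject": self.subject,
            "window_index": self.window_index,
            "r_value_mv": self.r_value,
            "hr_bpm": self.hr,
            "pnn50": self.pnn50,
            "binen": self.binen,
            "label": self.label,
        }


def detect_rpeaks(x: Signal, min_rri_ms: float = MIN_RRI_MS) -> RPeakSeries:
    """Detect R peaks; returns an empty series when nothing qualifies.

    Bandpass 5–25 Hz, square the derivative, integrate over 150 ms, pick
    peaks above an adaptive threshold at least ``min_rri_ms`` apart, then
    snap each to the raw-signal maximum within ±60 ms. Peaks that still
    leave an implausibly short interval are resolved in favour of the
    larger amplitude.
    """
    fs = x.fs
    raw = x.samples
    empty = RPeakSeries(np.array([], dtype=int), np.array([]), fs)
    if raw.size < int(2 * fs):
        return empty
    if np.ptp(raw) == 0.0:
        return empty

    nyq = fs / 2.0
    hi = min(25.0, 0.9 * nyq)
    b, a = sps.butter(2, [5.0 / nyq, hi / nyq], btype="band")
    filt = sps.filtfilt(b, a, raw)
    energy = np.gradient(filt) ** 2
    win = max(int(0.150 * fs), 1)
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    if integ.max() <= 0.0:
        return empty

    dist = max(int(min_rri_ms / 1000.0 * fs), 1)
    height = 0.15 * np.quantile(integ, 0.99)
    locs, _ = sps.find_peaks(integ, height=height, distance=dist)
    if locs.size == 0:
        return empty

    snap = max(int(0.060 * fs), 1)
    refined = []
    for loc in locs:
        lo, hi_ = max(loc - snap, 0), min(loc + snap + 1, raw.size)
        refined.append(lo + int(np.argmax(raw[lo:hi_])))
    idx = np.unique(refined)

    # enforce the refractory constraint after snapping: drop the smaller
    # of any pair closer than min_rri_ms
    keep = list(idx)
    changed = True
    while changed and len(keep) > 1:
        changed = False
        for i in range(len(keep) - 1):
            if (keep[i + 1] - keep[i]) / fs * 1000.0 < min_rri_ms:
                drop = i if raw[keep[i]] < raw[keep[i + 1]] else i + 1
                del keep[drop]
                changed = True
                break
    idx = np.asarray(keep, dtype=int)
    return RPeakSeries(idx, raw[idx], fs)


def heart_rate(rri_ms: np.ndarray | float) -> np.ndarray | float:
    """Instantaneous heart rate in beats/min: 60000 / RRI(ms)."""
    rri = np.asarray(rri_ms, dtype=float)
    if np.any(rri <= 0):
        raise ValueError("RR intervals must be positive")
    out = 60.0 / rri * 1000.0
    return float(out) if out.ndim == 0 else out


def pnnx(nn_ms: np.ndarray, x_ms: float = 50.0) -> float:
    """Fraction of successive NN-interval differences with |ΔNN| > x_ms.

    Returns NaN (undefined) when fewer than two intervals are available.
    """
    nn = np.asarray(nn_ms, dtype=float)
    if nn.size < 2:
        return math.nan
    dnn = np.abs(np.diff(nn))
    return float(np.mean(dnn > x_ms))


def window_features(
    x: Signal,
    window_s: float = 50.0,
    label: str | None = None,
    subject: str | None = None,
    binen_params: BinEnParams = BinEnParams(),
    pnn_threshold_ms: float = 50.0,
    r_value_stat: str = "mean",
    hr_mode: str = "mean_instantaneous",
    drop_log: list | None = None,
) -> list[FeatureVector]:
    """Cut ``x`` into non-overlapping windows and extract the 4 features.

    Windows with fewer than two detected R peaks are dropped (and logged
    into ``drop_log`` when given). ``r_value_stat`` selects mean or median
    R amplitude; ``hr_mode`` selects the mean of instantaneous rates or
    ``60000 / mean(RRI)``.
    """
    if r_value_stat not in ("mean", "median"):
        raise ValueError("r_value_stat must be 'mean' or 'median'")
    if hr_mode not in ("mean_instantaneous", "inverse_mean_rri"):
        raise ValueError("unknown hr_mode")
    win = int(window_s * x.fs)
    n_windows = len(x) // win
    out: list[FeatureVector] = []
    for w in range(n_windows):
        samples = x.samples[w * win : (w + 1) * win]
        sig = Signal(samples, x.fs)
        peaks = detect_rpeaks(sig)
        if len(peaks) < 2:
            if drop_log is not None:
                drop_log.append(
                    {"window_index": w, "subject": subject, "reason": "too few R peaks"}
                )
            continue
        rri = peaks.rri_ms
        if hr_mode == "mean_instantaneous":
            hr = float(np.mean(heart_rate(rri)))
        else:
            hr = float(heart_rate(float(np.mean(rri))))
        r_val = (
            float(np.mean(peaks.amplitudes))
            if r_value_stat == "mean"
            else float(np.median(peaks.amplitudes))
        )
        out.append(
            FeatureVector(
                r_value=r_val,
                hr=hr,
                pnn50=pnnx(rri, pnn_threshold_ms),
                binen=binen(samples, binen_params),
                label=label,
                subject=subject,
                window_index=w,
            )
        )
    return out
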