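"""Synthetic labeled cECG: known beats, HRV structure, artifacts, classes.

Beats are sums of five Gaussian bumps (P, Q, R, S, T) with widths and
offsets fixed relative to the local RR interval — not physiological
morphology, just a waveform with a dominant, exactly placed local maximum
at R, which is all the downstream pipeline relies on. Coarse artifacts are
rectangular transients with a superimposed oscillation, amplitudes many
times the R amplitude. Stress classes differ through the configured RR
mean/SD (high stress: faster, less variable heart rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from cecgstress.signal import Signal

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "gen_rr_series",
    "render_ecg",
    "inject_artifacts",
    "gen_labeled_dataset",
]

LOW_STRESS = "low_stress"
HIGH_STRESS = "high_stress"

# (amplitude rel. to R, center offset rel. to RR, width rel. to RR)
_BEAT_WAVES = {
    "P": (0.15, -0.22, 0.035),
    "Q": (-0.12, -0.045, 0.012),
    "R": (1.0, 0.0, 0.016),
    "S": (-0.20, 0.045, 0.014),
    "T": (0.30, 0.30, 0.060),
}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; none of the values is a claim about real data."""

    fs: float = 200.0
    duration_s: float = 60.0
    r_amp_mv: float = 1.0
    rr_mean_ms: float = 800.0
    rr_sd_ms: float = 40.0
    noise_sd_mv: float = 0.02
    artifact_rate_per_min: float = 0.0
    artifact_amp_mv: float = 10.0
    artifact_dur_s: float = 1.0
    drift_amp_mv: float = 0.0
    drift_freq_hz: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.rr_mean_ms <= 0:
            raise ValueError("rr_mean_ms must be positive")
        if self.rr_sd_ms < 0:
            raise ValueError("rr_sd_ms must be non-negative")
        if self.artifact_amp_mv < 0:
            raise ValueError("artifact_amp_mv must be non-negative")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    r_peak_indices: np.ndarray
    artifact_mask: np.ndarray
    class_label: str | None = None
    r_peaks_overwritten: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r_peak_indices = np.asarray(self.r_peak_indices, dtype=int)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if np.any(np.diff(self.r_peak_indices) <= 0):
            raise ValueError("r_peak_indices must be strictly increasing")


def gen_rr_series(
    n_beats: int, rr_mean_ms: float, rr_sd_ms: float, seed: int = 0
) -> np.ndarray:
    """Gaussian RR intervals (ms), truncated below at 250 ms."""
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if rr_mean_ms <= 0:
        raise ValueError("rr_mean_ms must be positive")
    if rr_sd_ms < 0:
        raise ValueError("rr_sd_ms must be non-negative")
    rng = np.random.default_rng(seed)
    rr = rng.normal(rr_mean_ms, rr_sd_ms, size=n_beats)
    return np.maximum(rr, 250.0)


def render_ecg(
    rr_series: np.ndarray,
    fs: float,
    r_amp_mv: float = 1.0,
    noise_sd_mv: float = 0.0,
    seed: int = 0,
) -> tuple[Signal, GroundTruth]:
    """Render one beat per RR interval; returns the trace and ground truth.

    The i-th R peak sits at the cumulative RR time (first peak after half
    an interval), rounded to the sample grid. The R-sample amplitude is
    forced to exactly ``r_amp_mv`` before noise, so a noise-free render
    has its per-beat global maximum at the recorded index.
    """
    rr = np.asarray(rr_series, dtype=float)
    if rr.size == 0:
        raise ValueError("rr_series must be non-empty")
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz to place a QRS template")

    r_times_s = (np.cumsum(rr) - rr[0] + 0.5 * rr[0]) / 1000.0
    r_idx = np.round(r_times_s * fs).astype(int)
    n = int(round((np.sum(rr) / 1000.0) * fs))
    x = np.zeros(n)

    for i, (ri, rr_ms) in enumerate(zip(r_idx, rr)):
        rr_samp = rr_ms / 1000.0 * fs
        for amp, off, width in _BEAT_WAVES.values():
            center = ri + off * rr_samp
            half = max(int(np.ceil(4 * width * rr_samp)), 2)
            lo = max(int(np.floor(center)) - half, 0)
            hi = min(int(np.ceil(center)) + half + 1, n)
            if lo >= hi:
                continue
            k = np.arange(lo, hi)
            x[lo:hi] += (
                amp
                * r_amp_mv
                * np.exp(-0.5 * ((k - center) / (width * rr_samp)) ** 2)
            )
    # pin the R sample to the exact configured amplitude
    for ri in r_idx:
        if 0 <= ri < n:
            x[ri] = r_amp_mv

    if noise_sd_mv > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd_mv, size=n)

    in_range = (r_idx >= 0) & (r_idx < n)
    gt = GroundTruth(
        r_peak_indices=r_idx[in_range],
        artifact_mask=np.zeros(n, dtype=bool),
    )
    return Signal(x, fs, {"source": "synthetic"}), gt


def inject_artifacts(
    signal: Signal, spec: SynthConfig, seed: int = 0
) -> tuple[Signal, np.ndarray]:
    """Add coarse motion transients; returns (signal, per-sample mask).

    The number of artifacts is ``round(rate_per_min * duration_min)``.
    Spans are placed on a non-overlapping slot grid so the requested
    coverage is met. With zero artifacts the input comes back unchanged.
    """
    n = len(signal)
    art_samples = int(round(spec.artifact_dur_s * signal.fs))
    n_art = int(round(spec.artifact_rate_per_min * signal.duration_s / 60.0))
    mask = np.zeros(n, dtype=bool)
    if n_art == 0 or spec.artifact_amp_mv == 0.0:
        return Signal(signal.samples.copy(), signal.fs, dict(signal.meta)), mask
    if art_samples > n:
        raise ValueError("artifact duration exceeds signal duration")
    n_slots = n // art_samples
    if n_art > n_slots:
        raise ValueError(
            f"{n_art} artifacts of {art_samples} samples do not fit in {n} samples"
        )
    rng = np.random.default_rng(seed)
    slots = rng.choice(n_slots, size=n_art, replace=False)

    out = signal.samples.copy()
    t = np.arange(art_samples) / signal.fs
    for s in slots:
        lo = s * art_samples
        hi = lo + art_samples
        sign = rng.choice((-1.0, 1.0))
        # rectangle + strong oscillation: visible both in amplitude and in
        # the fluctuation around a within-segment linear trend
        burst = sign * spec.artifact_amp_mv * (1.0 + 0.8 * np.sin(2 * np.pi * 5.0 * t))
        out[lo:hi] += burst
        mask[lo:hi] = True
    sig = Signal(out, signal.fs, dict(signal.meta, artifacts_injected=int(n_art)))
    return sig, mask


def _windows_from_config(
    cfg: SynthConfig,
    n_windows: int,
    window_s: float,
    subject_ids: list[str],
    label: str,
    rng: np.random.Generator,
) -> list[tuple[Signal, str, str]]:
    per_subject = int(np.ceil(n_windows / len(subject_ids)))
    out: list[tuple[Signal, str, str]] = []
    for subj in subject_ids:
        take = min(per_subject, n_windows - len(out))
        if take <= 0:
            break
        dur = take * window_s
        n_beats = int(np.ceil(dur * 1000.0 / cfg.rr_mean_ms)) + 4
        rr = gen_rr_series(
            n_beats, cfg.rr_mean_ms, cfg.rr_sd_ms, seed=int(rng.integers(2**31))
        )
        sig, _ = render_ecg(
            rr, cfg.fs, cfg.r_amp_mv, cfg.noise_sd_mv, seed=int(rng.integers(2**31))
        )
        if cfg.artifact_rate_per_min > 0:
            sig, _ = inject_artifacts(sig, cfg, seed=int(rng.integers(2**31)))
        win = int(window_s * cfg.fs)
        for w in range(take):
            samples = sig.samples[w * win : (w + 1) * win]
            if samples.size < win:
                break
            out.append(
                (Signal(samples, cfg.fs, {"subject": subj, "label": label}), label, subj)
            )
    return out


def gen_labeled_dataset(
    config_low: SynthConfig,
    config_high: SynthConfig,
    n_windows_per_class: int,
    seed: int = 0,
    window_s: float = 50.0,
    n_subjects: int = 10,
) -> list[tuple[Signal, str, str]]:
    """Fixed-length windows for two stress classes, tagged with subject ids.

    Every subject contributes windows of both classes so subject-grouped
    splits keep both labels in every fold. Identical class configs warn:
    the classes would not be separable by design.
    """
    if n_windows_per_class < 0:
        raise ValueError("n_windows_per_class must be >= 0")
    if (
        config_low.rr_mean_ms == config_high.rr_mean_ms
        and config_low.rr_sd_ms == config_high.rr_sd_ms
    ):
        warnings.warn(
            "low- and high-stress configs share rr_mean_ms and rr_sd_ms; "
            "classes are not separable by design",
            stacklevel=2,
        )
    if n_windows_per_class == 0:
        return []
    rng = np.random.default_rng(seed)
    subjects = [f"s{i:02d}" for i in range(n_subjects)]
    data = _windows_from_config(
        config_low, n_windows_per_class, window_s, subjects, LOW_STRESS, rng
    )
    data += _windows_from_config(
        config_high, n_windows_per_class, window_s, subjects, HIGH_STRESS, rng
    )
    return data
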