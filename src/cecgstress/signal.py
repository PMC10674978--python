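"""Core signal container. Amplitudes are millivolts everywhere."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class Signal:
    """A uniformly sampled single-channel (c)ECG trace.

    Parameters
    ----------
    samples : ndarray
        Amplitude in mV.
    fs : float
        Sampling frequency in Hz, > 0.
    meta : dict
        Free-form provenance (subject id, source file, stage names...).
    """

    samples: np.ndarray
    fs: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs
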