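"""Reading and writing the pipeline's on-disk formats.

Signals travel as two-column CSV (time_s, amplitude_mv); features as a
flat CSV table; metrics as JSON. Every file written here starts with a
comment header carrying the package version and a hash of the run
configuration so outputs are traceable. WFDB records are supported when
the optional ``wfdb`` package is installed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from cecgstress import __version__
from cecgstress.signal import Signal

__all__ = [
    "config_hash",
    "read_signal",
    "write_signal",
    "write_ground_truth",
    "write_feature_table",
    "read_feature_table",
    "write_metrics_json",
    "write_segment_report",
]

_JITTER_TOL = 0.01  # relative sampling-interval jitter allowed in CSV input


def config_hash(config: dict[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(cfg_hash: str | None) -> str:
    tag = cfg_hash if cfg_hash else "none"
    return f"# cecgstress v{__version__} config={tag}\n"


def read_signal(path: str | Path, format: str = "csv", channel: str | None = None) -> Signal:
    """Load a signal from CSV (time_s, amplitude_mv) or a WFDB record.

    CSV sampling frequency is the reciprocal of the median time step;
    irregular sampling beyond 1% jitter is rejected. For WFDB, ``path`` is
    the record name (no extension) and ``channel`` selects a signal name.
    """
    path = Path(path)
    if format == "csv":
        return _read_signal_csv(path)
    if format == "wfdb":
        return _read_signal_wfdb(path, channel)
    raise ValueError(f"unknown format {format!r}")


def _read_signal_csv(path: Path) -> Signal:
    if not path.exists():
        raise FileNotFoundError(path)
    times: list[float] = []
    amps: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if lineno == 1 or (not times and _is_header_row(parts)):
                if _is_header_row(parts):
                    continue
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                amps.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {line!r}") from exc
    if len(times) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(np.asarray(times))
    med = float(np.median(dt))
    if med <= 0:
        raise ValueError(f"{path}: non-increasing time column")
    if np.any(np.abs(dt - med) > _JITTER_TOL * med):
        raise ValueError(f"{path}: irregular sampling (> 1% jitter)")
    return Signal(np.asarray(amps), fs=1.0 / med, meta={"source": str(path)})


def _is_header_row(parts: list[str]) -> bool:
    try:
        float(parts[0])
        return False
    except ValueError:
        return True


def _read_signal_wfdb(path: Path, channel: str | None) -> Signal:
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package"
        ) from exc
    record = wfdb.rdrecord(str(path))
    names = list(record.sig_name)
    if channel is None:
        col = 0
    elif channel in names:
        col = names.index(channel)
    else:
        raise ValueError(f"channel {channel!r} not found; available: {names}")
    return Signal(
        np.asarray(record.p_signal[:, col], dtype=float),
        fs=float(record.fs),
        meta={"source": str(path), "channel": names[col]},
    )


def write_signal(signal: Signal, path: str | Path, cfg_hash: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash))
        fh.write("time_s,amplitude_mv\n")
        for t, v in zip(signal.time_s, signal.samples):
            fh.write(f"{t:.9g},{v:.9g}\n")
    return path


def write_ground_truth(
    n_samples: int,
    r_peak_indices: np.ndarray,
    artifact_mask: np.ndarray,
    path: str | Path,
    class_label: str | None = None,
    subject: str | None = None,
    cfg_hash: str | None = None,
) -> Path:
    """Sidecar CSV: sample_index, is_artifact, is_rpeak, class, subject."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    is_r = np.zeros(n_samples, dtype=bool)
    is_r[np.asarray(r_peak_indices, dtype=int)] = True
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash))
        fh.write("sample_index,is_artifact,is_rpeak,class,subject\n")
        for i in range(n_samples):
            fh.write(
                f"{i},{int(artifact_mask[i])},{int(is_r[i])},"
                f"{class_label or ''},{subject or ''}\n"
            )
    return path


def write_feature_table(
    features: pd.DataFrame, path: str | Path, cfg_hash: str | None = None
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash))
        features.to_csv(fh, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_metrics_json(metrics: dict, path: str | Path, cfg_hash: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"package_version": __version__, "config": cfg_hash or "none"}
    payload.update(metrics)
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "as_dict"):
        return obj.as_dict()
    raise TypeError(f"cannot serialize {type(obj)}")


def write_segment_report(result, path: str | Path, cfg_hash: str | None = None) -> Path:
    """Per-segment CSV: index, FD, eliminated flag and reason."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash))
        fh.write("segment_index,fd,eliminated,reason\n")
        for j, (fd_j, kept, reason) in enumerate(
            zip(result.fd, result.keep_mask, result.reasons)
        ):
            fh.write(f"{j},{fd_j:.9g},{int(not kept)},{reason.value}\n")
    return path
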