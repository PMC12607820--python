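"""Force-plate center-of-pressure (COP) conditioning.

Raw COP recordings arrive as two-channel (mediolateral x, anteroposterior
y) time series in millimetres, nominally sampled at 100 Hz.  The
conditioning chain low-pass filters each axis with a fourth-order 10 Hz
Butterworth filter and emits a mm-space :class:`~swaybalance.sway.Trajectory`
ready for sway-parameter computation.

Zero-phase (forward–backward) filtering is the default: it is standard in
posturography because phase lag would distort velocity-based sway metrics.
The effective magnitude response is then the design filter's squared —
gain 0.5 rather than 1/√2 at the cutoff.  A causal single-pass mode is
also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .sway import Trajectory

__all__ = [
    "CopRecording",
    "FilterSpec",
    "load_cop",
    "save_cop",
    "butterworth_lowpass",
    "cop_to_trajectory",
]

logger = logging.getLogger(__name__)

COP_COLUMNS = ("time_s", "cop_x_mm", "cop_y_mm")


@dataclass(frozen=True)
class CopRecording:
    """Raw or filtered two-channel COP signal in mm."""

    x_mm: np.ndarray
    y_mm: np.ndarray
    rate_hz: float = 100.0
    subject_id: str = ""
    condition: str = ""
    filtered: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_mm", np.asarray(self.x_mm, dtype=float))
        object.__setattr__(self, "y_mm", np.asarray(self.y_mm, dtype=float))
        if len(self.x_mm) != len(self.y_mm):
            raise ValueError("x and y series must have equal length")
        if len(self.x_mm) < 2:
            raise ValueError("COP recording needs at least 2 samples")
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if not (np.all(np.isfinite(self.x_mm)) and np.all(np.isfinite(self.y_mm))):
            raise ValueError("COP samples must be finite")

    def __len__(self) -> int:
        return len(self.x_mm)


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth design: order, −3 dB cutoff, and phase mode."""

    order: int = 4
    cutoff_hz: float = 10.0
    mode: str = "zero_phase"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        if not self.cutoff_hz > 0:
            raise ValueError(f"cutoff_hz must be positive, got {self.cutoff_hz}")
        if self.mode not in ("zero_phase", "causal"):
            raise ValueError(f"mode must be zero_phase or causal, got {self.mode!r}")


def load_cop(path: str | Path, rate_hz: float | None = None,
             subject_id: str = "", condition: str = "") -> CopRecording:
    """Read a COP CSV with columns time_s, cop_x_mm, cop_y_mm.

    The sampling rate is inferred from the median time step unless
    ``rate_hz`` is given; a >1% mismatch between the two logs a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise OSError(f"cannot read COP file {path}: {exc}") from exc

    missing = [c for c in COP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(df) < 2:
        raise ValueError(f"{path}: need at least 2 rows, got {len(df)}")
    for col in COP_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at data row {row}"
            )
        df[col] = numeric

    dt = float(np.median(np.diff(df["time_s"].to_numpy())))
    inferred = 1.0 / dt if dt > 0 else None
    if rate_hz is None:
        if inferred is None:
            raise ValueError(f"{path}: cannot infer rate from time column")
        rate_hz = inferred
    elif inferred is not None and abs(inferred - rate_hz) / rate_hz > 0.01:
        logger.warning(
            "%s: declared rate %.3f Hz differs from inferred %.3f Hz by >1%%",
            path, rate_hz, inferred,
        )
    return CopRecording(
        x_mm=df["cop_x_mm"].to_numpy(),
        y_mm=df["cop_y_mm"].to_numpy(),
        rate_hz=rate_hz,
        subject_id=subject_id,
        condition=condition,
    )


def save_cop(rec: CopRecording, path: str | Path) -> None:
    """Write a recording to the package's plain COP CSV format."""
    t = np.arange(len(rec)) / rec.rate_hz
    pd.DataFrame(
        {"time_s": t, "cop_x_mm": rec.x_mm, "cop_y_mm": rec.y_mm}
    ).to_csv(path, index=False, float_format="%.10g")


def butterworth_lowpass(rec: CopRecording, spec: FilterSpec | None = None) -> CopRecording:
    """Low-pass filter both axes; output length equals input length.

    Zero-phase mode runs the design filter forward then backward
    (scipy ``filtfilt`` with odd reflective padding of 3×(order+1)
    samples), causal mode runs it once.
    """
    spec = spec or FilterSpec()
    nyquist = rec.rate_hz / 2
    if spec.cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist {nyquist} Hz"
        )
    padlen = 3 * (spec.order + 1)
    if len(rec) <= padlen:
        raise ValueError(
            f"series of {len(rec)} samples too short for edge padding "
            f"({padlen} samples)"
        )
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="low",
                        fs=rec.rate_hz, output="sos")
    if spec.mode == "zero_phase":
        filt = lambda s: signal.sosfiltfilt(sos, s, padtype="odd", padlen=padlen)
    else:
        filt = lambda s: signal.sosfilt(sos, s)
    logger.info(
        "Butterworth low-pass: order %d, cutoff %g Hz, mode %s",
        spec.order, spec.cutoff_hz, spec.mode,
    )
    return replace(rec, x_mm=filt(rec.x_mm), y_mm=filt(rec.y_mm), filtered=True)


def cop_to_trajectory(rec: CopRecording) -> Trajectory:
    """Convert a (filtered) recording to a mm-space trajectory.

    Passing an unfiltered recording is allowed but logs a warning — sway
    velocities computed from raw plate signals are inflated by noise.
    """
    if not rec.filtered:
        logger.warning(
            "converting an unfiltered COP recording to a trajectory; "
            "velocity parameters will include measurement noise"
        )
    return Trajectory(x=rec.x_mm, y=rec.y_mm, rate_hz=rec.rate_hz, units="mm")
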