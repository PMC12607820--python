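"""Sway parameters: the nine stabilometric metrics computed from a 2-D trajectory.

The same computation is applied to pixel-space COM paths from video and
mm-space COP paths from a force plate; comparison between the two
modalities happens at the parameter level, never sample-by-sample.

Per axis a ∈ {x, y, r}:

* ``Vmean_a``  — mean oscillation velocity: mean of the instantaneous
  speed series ``|d_a[i]| * rate`` (units/s).  Equivalent to path length
  over analyzed duration.
* ``Vstd_a``   — sample standard deviation (n−1) of the instantaneous
  speed series (units/s).
* ``Ctotal_a`` — total displacement: cumulative path length
  ``Σ|d_a[i]|`` (units).

x is mediolateral, y anteroposterior, and r the radial resultant with
per-step length ``√(dx² + dy²)``.  The identity
``Vmean_a * duration = Ctotal_a`` holds algebraically on every input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Trajectory",
    "StepSeries",
    "SwayParameters",
    "step_displacements",
    "compute_sway_parameters",
    "scale_trajectory",
    "PARAMETER_ORDER",
]

#: Canonical parameter column order (used for CSV output and deterministic
#: tie-breaking in predictor selection).
PARAMETER_ORDER = (
    "Vmean_x", "Vmean_y", "Vmean_r",
    "Vstd_x", "Vstd_y", "Vstd_r",
    "Ctotal_x", "Ctotal_y", "Ctotal_r",
)

_VALID_UNITS = ("pixel", "mm")


@dataclass(frozen=True)
class Trajectory:
    """A 2-D (x, y) time series sampled at a fixed rate.

    x: mediolateral samples; y: anteroposterior samples (for video, the
    image-plane row coordinate used as an anteroposterior proxy).
    """

    x: np.ndarray
    y: np.ndarray
    rate_hz: float
    units: str = "pixel"

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ValueError("trajectory axes must be 1-D")
        if len(self.x) != len(self.y):
            raise ValueError(
                f"x and y lengths differ: {len(self.x)} vs {len(self.y)}"
            )
        if len(self.x) < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if not (self.rate_hz > 0):
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.units not in _VALID_UNITS:
            raise ValueError(f"units must be one of {_VALID_UNITS}, got {self.units!r}")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("trajectory samples must be finite")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        """Analyzed duration (n−1)/rate — the time spanned by the steps."""
        return (len(self.x) - 1) / self.rate_hz


@dataclass(frozen=True)
class StepSeries:
    """Per-step signed displacements and Euclidean step lengths."""

    dx: np.ndarray
    dy: np.ndarray
    dr: np.ndarray
    dt: float


@dataclass(frozen=True)
class SwayParameters:
    """The nine per-trial sway metrics (velocities in units/s, displacements in units)."""

    vmean_x: float
    vmean_y: float
    vmean_r: float
    vstd_x: float
    vstd_y: float
    vstd_r: float
    ctotal_x: float
    ctotal_y: float
    ctotal_r: float
    units: str
    duration_s: float

    def as_dict(self, modality: str | None = None) -> dict[str, float]:
        """Flatten to Table-style column names, e.g. ``Vmean_COMx`` for modality='COM'."""
        tag = modality or ""
        vals = (
            self.vmean_x, self.vmean_y, self.vmean_r,
            self.vstd_x, self.vstd_y, self.vstd_r,
            self.ctotal_x, self.ctotal_y, self.ctotal_r,
        )
        out = {}
        for name, v in zip(PARAMETER_ORDER, vals):
            stat, axis = name.rsplit("_", 1)
            out[f"{stat}_{tag}{axis}"] = v
        return out


def step_displacements(traj: Trajectory) -> StepSeries:
    """First differences of the trajectory: dx, dy, and dr = √(dx²+dy²)."""
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    dr = np.hypot(dx, dy)
    return StepSeries(dx=dx, dy=dy, dr=dr, dt=1.0 / traj.rate_hz)


def _axis_stats(d: np.ndarray, rate_hz: float) -> tuple[float, float, float]:
    speed = np.abs(d) * rate_hz
    vmean = float(np.mean(speed))
    vstd = float(np.std(speed, ddof=1)) if len(speed) > 1 else 0.0
    ctotal = float(np.sum(np.abs(d)))
    return vmean, vstd, ctotal


def compute_sway_parameters(traj: Trajectory) -> SwayParameters:
    """Compute all nine sway parameters for one trial."""
    steps = step_displacements(traj)
    vmx, vsx, ctx = _axis_stats(steps.dx, traj.rate_hz)
    vmy, vsy, cty = _axis_stats(steps.dy, traj.rate_hz)
    vmr, vsr, ctr = _axis_stats(steps.dr, traj.rate_hz)
    return SwayParameters(
        vmean_x=vmx, vmean_y=vmy, vmean_r=vmr,
        vstd_x=vsx, vstd_y=vsy, vstd_r=vsr,
        ctotal_x=ctx, ctotal_y=cty, ctotal_r=ctr,
        units=traj.units, duration_s=traj.duration_s,
    )


def scale_trajectory(traj: Trajectory, mm_per_pixel: float) -> Trajectory:
    """Convert a pixel-space trajectory to mm with a calibration factor.

    Every sway parameter is homogeneous of degree 1 in the coordinates, so
    this scales all nine parameters by the same factor.  The factor comes
    from a calibration object of known width W mm spanning P px:
    ``mm_per_pixel = W / P``.
    """
    if traj.units != "pixel":
        raise ValueError(f"expected pixel units, got {traj.units!r}")
    if not (mm_per_pixel > 0):
        raise ValueError(f"mm_per_pixel must be positive, got {mm_per_pixel}")
    return replace(
        traj, x=traj.x * mm_per_pixel, y=traj.y * mm_per_pixel, units="mm"
    )
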