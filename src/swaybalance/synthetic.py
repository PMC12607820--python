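"""Synthetic paired video/COP generator with known ground-truth sway.

Emulates the study design the package is built to analyze: 30-second
quiet-stance trials in four conditions (eyes open/closed × feet
apart/together), with a CP-like group swaying more and faster than a
control-like group, and a force-plate COP signal coupled to the video
COM trajectory.

The sway model is band-limited Gaussian noise: white noise per axis,
low-pass filtered to a bandwidth, then rescaled so each axis's sample SD
equals a target amplitude.  This is the simplest stationary process with
independently controllable amplitude and bandwidth — a test substrate,
not a biomechanical model of cerebral-palsy sway.

Videos are rendered as a textured ellipse ("trunk blob") rigidly
translating over a plain background, so frame differencing registers
interior texture motion as well as edge motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .cop import CopRecording
from .sway import Trajectory
from .video import FrameSequence
from .videoio import write_avi

__all__ = [
    "SwayModelParams",
    "RenderParams",
    "CohortSpec",
    "CONDITIONS",
    "SyntheticTrial",
    "simulate_sway_trajectory",
    "render_silhouette_video",
    "simulate_cop_from_com",
    "generate_cohort",
    "write_cohort",
]

#: The four quiet-stance test conditions, in protocol order.
CONDITIONS = (
    "eyes_open_feet_apart",
    "eyes_closed_feet_apart",
    "eyes_open_feet_together",
    "eyes_closed_feet_together",
)


@dataclass(frozen=True)
class SwayModelParams:
    """Band-limited Gaussian sway model.

    Amplitudes are RMS displacements per axis (pixel for rendering,
    interpreted at the renderer's scale); ``bandwidth_hz`` bounds the
    sway power spectrum from above.
    """

    amplitude_x: float = 6.0
    amplitude_y: float = 4.0
    bandwidth_hz: float = 1.0
    duration_s: float = 30.0
    rate_hz: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_x < 0:
            raise ValueError(f"amplitude_x must be >= 0, got {self.amplitude_x}")
        if self.amplitude_y < 0:
            raise ValueError(f"amplitude_y must be >= 0, got {self.amplitude_y}")
        if not (0 < self.bandwidth_hz < self.rate_hz / 2):
            raise ValueError(
                f"bandwidth_hz must be in (0, rate_hz/2), got {self.bandwidth_hz}"
            )
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")


@dataclass(frozen=True)
class RenderParams:
    """Silhouette-video rendering: frame geometry, blob size, intensities."""

    frame_width: int = 64
    frame_height: int = 96
    silhouette_half_width: float = 12.0
    silhouette_half_height: float = 24.0
    background_level: float = 0.95
    foreground_level: float = 0.5
    texture_contrast: float = 0.5
    texture_wavelength_px: float = 6.0
    fps: float = 30.0

    def __post_init__(self) -> None:
        for name in ("background_level", "foreground_level", "texture_contrast"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.silhouette_half_width <= 0 or self.silhouette_half_height <= 0:
            raise ValueError("silhouette half-sizes must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group, four-condition study layout.

    ``cp_amplitude_multiplier`` scales the CP-like group's sway
    amplitudes; ``condition_multipliers`` scale sway per stance
    condition, ordered as :data:`CONDITIONS` (harder stances sway more).
    ``coupling_noise_sd`` (mm) decouples COP from COM.
    ``subject_amplitude_cv`` adds log-normal per-subject amplitude
    variability (shared across a subject's conditions), giving the
    continuous between-subject spread real cohorts show.
    """

    n_cp: int = 20
    n_control: int = 20
    cp_amplitude_multiplier: float = 2.0
    condition_multipliers: tuple[float, float, float, float] = (1.0, 1.3, 1.5, 2.0)
    coupling_noise_sd: float = 0.2
    tremor_amplitude_mm: float = 0.5
    pixel_to_mm: float = 1.0
    subject_amplitude_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cp < 0 or self.n_control < 0:
            raise ValueError("group sizes must be >= 0")
        if self.cp_amplitude_multiplier <= 0:
            raise ValueError("cp_amplitude_multiplier must be > 0")
        if len(self.condition_multipliers) != len(CONDITIONS):
            raise ValueError(
                f"need {len(CONDITIONS)} condition multipliers, "
                f"got {len(self.condition_multipliers)}"
            )
        if any(m <= 0 for m in self.condition_multipliers):
            raise ValueError("condition multipliers must be > 0")
        if self.coupling_noise_sd < 0:
            raise ValueError("coupling_noise_sd must be >= 0")
        if self.subject_amplitude_cv < 0:
            raise ValueError("subject_amplitude_cv must be >= 0")


@dataclass(frozen=True)
class SyntheticTrial:
    """One subject × condition: ground truth plus both measurement modalities."""

    subject_id: str
    group: str
    condition: str
    truth: Trajectory
    video: FrameSequence | None
    cop: CopRecording
    amplitude_x: float
    amplitude_y: float
    seed: int


def simulate_sway_trajectory(params: SwayModelParams) -> Trajectory:
    """Generate a zero-mean band-limited Gaussian sway trajectory.

    White Gaussian noise per axis is low-pass filtered (zero-phase
    Butterworth at ``bandwidth_hz``), mean-removed, then rescaled so the
    sample SD of each axis equals its amplitude exactly.  Identical
    parameters and seed give identical output.
    """
    n = round(params.duration_s * params.rate_hz)
    if n < 2:
        raise ValueError("duration_s × rate_hz must give at least 2 samples")
    rng = np.random.default_rng(params.seed)
    sos = signal.butter(4, params.bandwidth_hz, btype="low",
                        fs=params.rate_hz, output="sos")

    def one_axis(amplitude: float) -> np.ndarray:
        white = rng.standard_normal(n)
        if amplitude == 0:
            return np.zeros(n)
        smooth = signal.sosfiltfilt(sos, white)
        smooth = smooth - smooth.mean()
        sd = smooth.std(ddof=0)
        if sd == 0:  # pathological draw; keep zero rather than divide
            return np.zeros(n)
        return smooth * (amplitude / sd)

    return Trajectory(
        x=one_axis(params.amplitude_x),
        y=one_axis(params.amplitude_y),
        rate_hz=params.rate_hz,
        units="pixel",
    )


def _triangle_wave(x: np.ndarray) -> np.ndarray:
    """Unit-amplitude triangle wave with period 1."""
    return 4.0 * np.abs(x - np.floor(x + 0.5)) - 1.0


def _texture(u: np.ndarray, v: np.ndarray, render: RenderParams) -> np.ndarray:
    """Fixed spatial pattern in blob coordinates (translates rigidly).

    A separable triangle-wave plaid: its intensity gradient has constant
    magnitude ``2·texture_contrast/wavelength`` per axis everywhere, so a
    rigid sub-pixel shift changes interior intensities uniformly rather
    than only along sparse stripes — the property frame differencing at a
    fixed threshold needs to register interior motion.
    """
    lam = render.texture_wavelength_px
    return 0.5 * render.texture_contrast * (
        _triangle_wave(u / lam) + _triangle_wave(v / lam)
    )


def render_silhouette_video(traj: Trajectory, render: RenderParams) -> FrameSequence:
    """Render one frame per trajectory sample: a textured ellipse on a
    plain background, centred at frame centre + trajectory offset.

    Trajectory coordinates are pixel offsets from the frame centre
    (x rightward, y downward).  Raises if the silhouette would leave the
    frame, reporting the first offending sample.
    """
    cx0 = render.frame_width / 2
    cy0 = render.frame_height / 2
    cx = cx0 + traj.x
    cy = cy0 + traj.y

    bad = np.flatnonzero(
        (cx - render.silhouette_half_width < 0)
        | (cx + render.silhouette_half_width > render.frame_width - 1)
        | (cy - render.silhouette_half_height < 0)
        | (cy + render.silhouette_half_height > render.frame_height - 1)
    )
    if len(bad):
        raise ValueError(
            f"silhouette exits the frame at sample {bad[0]} "
            f"(centre {cx[bad[0]]:.1f}, {cy[bad[0]]:.1f})"
        )

    rows = np.arange(render.frame_height)[:, None]
    cols = np.arange(render.frame_width)[None, :]
    frames = np.empty(
        (len(traj), render.frame_height, render.frame_width), dtype=np.float32
    )
    for i in range(len(traj)):
        u = cols - cx[i]
        v = rows - cy[i]
        inside = (
            (u / render.silhouette_half_width) ** 2
            + (v / render.silhouette_half_height) ** 2
        ) <= 1.0
        frame = np.full(
            (render.frame_height, render.frame_width),
            render.background_level, dtype=np.float64,
        )
        frame[inside] = render.foreground_level + _texture(u, v, render)[inside]
        frames[i] = np.clip(frame, 0.0, 1.0)
    return FrameSequence(frames=frames, fps=render.fps)


def simulate_cop_from_com(
    com: Trajectory,
    pixel_to_mm: float = 1.0,
    coupling_noise_sd: float = 0.0,
    tremor_amplitude: float = 0.0,
    seed: int = 0,
    cop_rate_hz: float = 100.0,
    tremor_freq_hz: float = 30.0,
) -> CopRecording:
    """Derive a plate-like COP signal from a COM trajectory.

    The COM path is linearly resampled to the plate rate (100 Hz),
    scaled to mm, then corrupted with independent Gaussian coupling
    noise and a supra-cutoff sinusoidal tremor that the Butterworth
    stage should largely remove.
    """
    if len(com) < 2:
        raise ValueError("COM trajectory needs at least 2 samples")
    if not pixel_to_mm > 0:
        raise ValueError(f"pixel_to_mm must be positive, got {pixel_to_mm}")

    t_com = np.arange(len(com)) / com.rate_hz
    n_out = int(np.floor(t_com[-1] * cop_rate_hz + 1e-9)) + 1
    t_cop = np.arange(n_out) / cop_rate_hz
    x = np.interp(t_cop, t_com, com.x) * pixel_to_mm
    y = np.interp(t_cop, t_com, com.y) * pixel_to_mm

    rng = np.random.default_rng(seed)
    if coupling_noise_sd > 0:
        x = x + rng.normal(0, coupling_noise_sd, len(x))
        y = y + rng.normal(0, coupling_noise_sd, len(y))
    if tremor_amplitude > 0:
        phase_x, phase_y = rng.uniform(0, 2 * np.pi, 2)
        x = x + tremor_amplitude * np.sin(2 * np.pi * tremor_freq_hz * t_cop + phase_x)
        y = y + tremor_amplitude * np.sin(2 * np.pi * tremor_freq_hz * t_cop + phase_y)
    return CopRecording(x_mm=x, y_mm=y, rate_hz=cop_rate_hz)


def _fit_frame(traj: Trajectory, render: RenderParams) -> RenderParams:
    """Grow the frame (never shrink) so this trial's silhouette stays inside.

    Gaussian sway is unbounded, so a fixed frame would fail on rare large
    excursions; the configured frame size acts as a minimum.  Frame sizes
    are kept even so the centre stays on a half-pixel grid.
    """
    need_w = 2 * int(np.ceil(np.abs(traj.x).max() + render.silhouette_half_width)) + 4
    need_h = 2 * int(np.ceil(np.abs(traj.y).max() + render.silhouette_half_height)) + 4
    w = max(render.frame_width, need_w + need_w % 2)
    h = max(render.frame_height, need_h + need_h % 2)
    if (w, h) == (render.frame_width, render.frame_height):
        return render
    return replace(render, frame_width=w, frame_height=h)


def generate_cohort(
    spec: CohortSpec,
    base: SwayModelParams | None = None,
    render: RenderParams | None = None,
    render_video: bool = True,
) -> list[SyntheticTrial]:
    """Generate the full subject × condition grid of paired trials.

    CP-like subjects use amplitudes × ``cp_amplitude_multiplier``;
    condition c uses amplitudes × ``condition_multipliers[c]``.  Each
    trial draws its own sub-seed from the cohort seed, so the whole
    dataset is a pure function of (spec, base, render).  Rendering can
    be switched off where only trajectories and COP signals are needed.
    """
    base = base or SwayModelParams()
    render = render or RenderParams()

    seed_seq = np.random.SeedSequence(spec.seed)
    trials: list[SyntheticTrial] = []
    subjects = [("cp", i) for i in range(spec.n_cp)] + [
        ("control", i) for i in range(spec.n_control)
    ]
    subject_rng = np.random.default_rng(seed_seq.spawn(1)[0])
    if spec.subject_amplitude_cv > 0:
        sigma = np.sqrt(np.log1p(spec.subject_amplitude_cv**2))
        subject_factors = subject_rng.lognormal(
            -(sigma**2) / 2, sigma, len(subjects)
        )
    else:
        subject_factors = np.ones(len(subjects))

    for (group, i), subj_factor in zip(subjects, subject_factors):
        group_mult = spec.cp_amplitude_multiplier if group == "cp" else 1.0
        subject_id = f"{group}{i:03d}"
        for c, condition in enumerate(CONDITIONS):
            child = seed_seq.spawn(1)[0]
            trial_seed = int(child.generate_state(1)[0] % (2**31))
            mult = group_mult * spec.condition_multipliers[c] * subj_factor
            params = replace(
                base,
                amplitude_x=base.amplitude_x * mult,
                amplitude_y=base.amplitude_y * mult,
                seed=trial_seed,
            )
            truth = simulate_sway_trajectory(params)
            if render_video:
                video = render_silhouette_video(truth, _fit_frame(truth, render))
            else:
                video = None
            cop = simulate_cop_from_com(
                truth,
                pixel_to_mm=spec.pixel_to_mm,
                coupling_noise_sd=spec.coupling_noise_sd,
                tremor_amplitude=spec.tremor_amplitude_mm,
                seed=trial_seed + 1,
            )
            cop = replace(cop, subject_id=subject_id, condition=condition)
            trials.append(SyntheticTrial(
                subject_id=subject_id,
                group=group,
                condition=condition,
                truth=truth,
                video=video,
                cop=cop,
                amplitude_x=params.amplitude_x,
                amplitude_y=params.amplitude_y,
                seed=trial_seed,
            ))
    return trials


def write_cohort(trials: list[SyntheticTrial], out_dir: str | Path) -> pd.DataFrame:
    """Write videos (AVI), COP CSVs, ground-truth CSVs, and a trial manifest.

    Returns the manifest (one row per trial: ids, labels, seeds, file
    paths, true amplitudes), also written to ``manifest.csv``.
    """
    from .cop import save_cop

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        stem = f"{trial.subject_id}_{trial.condition}"
        video_path = ""
        if trial.video is not None:
            video_path = str(out_dir / f"{stem}.avi")
            write_avi(video_path, trial.video.frames, trial.video.fps)
        cop_path = out_dir / f"{stem}_cop.csv"
        save_cop(trial.cop, cop_path)
        truth_path = out_dir / f"{stem}_truth.csv"
        pd.DataFrame({
            "time_s": np.arange(len(trial.truth)) / trial.truth.rate_hz,
            "x_px": trial.truth.x,
            "y_px": trial.truth.y,
        }).to_csv(truth_path, index=False, float_format="%.10g")
        rows.append({
            "subject_id": trial.subject_id,
            "group": trial.group,
            "condition": trial.condition,
            "seed": trial.seed,
            "video_path": video_path,
            "cop_path": str(cop_path),
            "truth_path": str(truth_path),
            "amplitude_x": trial.amplitude_x,
            "amplitude_y": trial.amplitude_y,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
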