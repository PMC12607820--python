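"""End-to-end orchestration: trials → per-trial parameter tables → validation.

Glues the stages together the way a study analysis would: every trial's
video goes through the motion-tracking pipeline into image (COM)
parameters, every COP recording through the Butterworth chain into plate
parameters, and the two tables meet in :func:`swaybalance.stats.run_validation`.
"""

from __future__ import annotations

from collections.abc import Iterable

import pandas as pd

from .cop import CopRecording, FilterSpec, butterworth_lowpass, cop_to_trajectory
from .stats import run_validation  # re-exported for convenience
from .sway import Trajectory, compute_sway_parameters
from .synthetic import SyntheticTrial
from .video import MotionConfig, extract_com_trajectory

__all__ = [
    "image_parameter_table",
    "cop_parameter_table",
    "truth_parameter_table",
    "run_validation",
]


def _row(trial_keys: dict, traj: Trajectory, modality: str) -> dict:
    return {**trial_keys, **compute_sway_parameters(traj).as_dict(modality)}


def image_parameter_table(
    trials: Iterable[SyntheticTrial],
    cfg: MotionConfig | None = None,
) -> pd.DataFrame:
    """Track each trial's video and compute COM sway parameters (pixel units)."""
    rows = []
    for t in trials:
        if t.video is None:
            raise ValueError(f"trial {t.subject_id}/{t.condition} has no video")
        traj = extract_com_trajectory(t.video, cfg=cfg)
        rows.append(_row(
            {"subject_id": t.subject_id, "group": t.group, "condition": t.condition},
            traj, "COM",
        ))
    return pd.DataFrame(rows)


def cop_parameter_table(
    trials_or_recordings: Iterable,
    spec: FilterSpec | None = None,
) -> pd.DataFrame:
    """Filter each COP recording and compute plate sway parameters (mm units)."""
    rows = []
    for item in trials_or_recordings:
        rec: CopRecording = item.cop if isinstance(item, SyntheticTrial) else item
        filtered = butterworth_lowpass(rec, spec)
        traj = cop_to_trajectory(filtered)
        rows.append(_row(
            {"subject_id": rec.subject_id,
             "group": item.group if isinstance(item, SyntheticTrial) else "",
             "condition": rec.condition},
            traj, "COP",
        ))
    return pd.DataFrame(rows)


def truth_parameter_table(trials: Iterable[SyntheticTrial]) -> pd.DataFrame:
    """Sway parameters of the generator's ground-truth COM trajectories.

    Uses the image-parameter column names, so the table can stand in for
    the tracked table wherever rendering/tracking noise is not the thing
    under study (e.g. large statistical power loops).
    """
    return pd.DataFrame([
        _row(
            {"subject_id": t.subject_id, "group": t.group, "condition": t.condition},
            t.truth, "COM",
        )
        for t in trials
    ])
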