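"""Video pipeline: ROI cropping, normalization, frame-difference motion
detection, morphological denoising, and silhouette-centroid tracking.

The pipeline turns a static-camera video of a standing subject into a
pixel-space center-of-mass (COM) trajectory:

(a) crop to a trunk region of interest and min-max normalize each frame;
(b) threshold the absolute intensity difference of consecutive frames
    (default cutoff 0.15) into a binary motion mask;
(c) clean the mask with morphological opening/closing and small-component
    removal;
(d) take the geometric centroid of the remaining moving pixels per frame
    pair, yielding an (N−1)-sample trajectory at the video frame rate.

Coordinates are 0-based image-plane pixels: x = column (mediolateral),
y = row (anteroposterior proxy in a frontal view; increases downward).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import morphology

from .sway import Trajectory
from .videoio import read_avi

__all__ = [
    "FrameSequence",
    "RegionOfInterest",
    "BinaryMotionMask",
    "MotionConfig",
    "load_video",
    "preprocess",
    "frame_difference_mask",
    "denoise_mask",
    "extract_com_trajectory",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrameSequence:
    """Ordered grayscale frames (T, H, W) with intensities on [0, 1]."""

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "frames", np.asarray(self.frames, dtype=np.float32)
        )
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.frames.shape[0] < 2:
            raise ValueError(
                f"need at least 2 frames to difference, got {self.frames.shape[0]}"
            )
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open pixel box [left, right) × [top, bottom), 0-based."""

    left: int
    top: int
    right: int
    bottom: int

    def validate(self, width: int, height: int) -> None:
        if not (0 <= self.left < self.right <= width):
            raise ValueError(
                f"ROI x-range [{self.left}, {self.right}) invalid for width {width}"
            )
        if not (0 <= self.top < self.bottom <= height):
            raise ValueError(
                f"ROI y-range [{self.top}, {self.bottom}) invalid for height {height}"
            )

    @classmethod
    def full_frame(cls, width: int, height: int) -> "RegionOfInterest":
        return cls(0, 0, width, height)


@dataclass(frozen=True)
class BinaryMotionMask:
    """Binary motion mask for the frame pair ending at ``frame_index``."""

    mask: np.ndarray
    frame_index: int


@dataclass(frozen=True)
class MotionConfig:
    """Tunables for motion detection and mask cleanup.

    ``threshold`` is the intensity-difference cutoff separating static
    from moving pixels.  Morphology defaults are sized to remove
    single-pixel speckle while preserving a trunk-scale silhouette.
    """

    threshold: float = 0.15
    morph_open_radius: int = 1
    morph_close_radius: int = 2
    min_component_area: int = 20
    empty_mask_policy: str = "carry_forward"
    normalization: str = "per_frame"

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.morph_open_radius < 0 or self.morph_close_radius < 0:
            raise ValueError("morphology radii must be >= 0")
        if self.min_component_area < 0:
            raise ValueError("min_component_area must be >= 0")
        if self.empty_mask_policy not in ("carry_forward", "mark_missing"):
            raise ValueError(
                f"unknown empty_mask_policy {self.empty_mask_policy!r}"
            )
        if self.normalization not in ("per_frame", "global", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def load_video(path: str | Path, fps: float | None = None) -> FrameSequence:
    """Load an MP4 or AVI video as grayscale frames on [0, 1].

    Uncompressed AVI is read natively.  Other containers/codecs (MP4 in
    particular) are decoded through imageio when an ffmpeg backend is
    installed (``pip install swaybalance[mp4]``).  Color frames are
    converted to grayscale with ITU-R BT.601 luma weights.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"video file not found: {path}")

    frames = meta_fps = None
    if path.suffix.lower() == ".avi":
        try:
            frames, meta_fps = read_avi(path)
        except ValueError:
            pass  # compressed AVI: fall through to imageio
    if frames is None:
        try:
            import imageio.v3 as iio

            raw = iio.imread(path)
            meta = iio.immeta(path)
            meta_fps = meta.get("fps")
        except ImportError as exc:
            raise OSError(
                f"cannot decode {path}: install the 'mp4' extra "
                "(imageio + ffmpeg backend) for compressed video"
            ) from exc
        raw = np.asarray(raw)
        if raw.ndim == 4:  # color → luma
            raw = raw[..., :3] @ np.array([0.299, 0.587, 0.114])
        frames = raw.astype(np.float32)
        if frames.max() > 1.0:
            frames /= 255.0

    if fps is None:
        fps = meta_fps
    if fps is None:
        raise ValueError(
            f"{path} carries no frame-rate metadata; pass fps explicitly"
        )
    seq = FrameSequence(frames=frames, fps=float(fps))
    logger.info("loaded %s: %d frames at %.3f fps", path, seq.n_frames, seq.fps)
    return seq


def _normalize_frame(frame: np.ndarray) -> np.ndarray:
    lo, hi = frame.min(), frame.max()
    if hi > lo:
        return (frame - lo) / (hi - lo)
    return np.zeros_like(frame)


def preprocess(seq: FrameSequence, roi: RegionOfInterest,
               cfg: MotionConfig | None = None) -> FrameSequence:
    """Crop to the ROI and normalize intensities to [0, 1].

    Per-frame min-max normalization (default) neutralizes global
    brightness flicker; a constant frame maps to all-zeros rather than
    dividing by zero.  ``cfg.normalization`` selects per-frame, global
    (one min-max over the whole clip), or none.
    """
    roi.validate(seq.width, seq.height)
    mode = (cfg or MotionConfig()).normalization
    cropped = seq.frames[:, roi.top:roi.bottom, roi.left:roi.right]
    if mode == "per_frame":
        out = np.stack([_normalize_frame(f) for f in cropped])
    elif mode == "global":
        out = _normalize_frame(cropped)
    else:
        out = cropped.copy()
    return FrameSequence(frames=out, fps=seq.fps)


def frame_difference_mask(prev: np.ndarray, curr: np.ndarray,
                          cfg: MotionConfig) -> np.ndarray:
    """Binary mask: 1 where |curr − prev| exceeds the threshold, else 0.

    A difference exactly equal to the threshold counts as static (0).
    """
    prev = np.asarray(prev)
    curr = np.asarray(curr)
    if prev.shape != curr.shape:
        raise ValueError(f"frame shapes differ: {prev.shape} vs {curr.shape}")
    return (np.abs(curr.astype(np.float64) - prev) > cfg.threshold).astype(np.uint8)


def denoise_mask(mask: np.ndarray, cfg: MotionConfig) -> np.ndarray:
    """Morphological opening then closing, then small-component removal.

    Opening (disk of radius ``morph_open_radius``) kills speckle, closing
    (radius ``morph_close_radius``) bridges small gaps, and connected
    components (8-connectivity) smaller than ``min_component_area``
    pixels are discarded.
    """
    out = mask.astype(bool)
    if cfg.morph_open_radius > 0:
        out = morphology.opening(out, morphology.disk(cfg.morph_open_radius))
    if cfg.morph_close_radius > 0:
        out = morphology.closing(out, morphology.disk(cfg.morph_close_radius))
    if cfg.min_component_area > 0:
        labels, n = ndimage.label(out, structure=np.ones((3, 3)))  # 8-connectivity
        if n:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            out = (sizes >= cfg.min_component_area)[labels] & out
    return out.astype(np.uint8)


def _centroid(mask: np.ndarray) -> tuple[float, float] | None:
    """(x=mean column, y=mean row) of 1-pixels, or None for an empty mask."""
    if not mask.any():
        return None
    cy, cx = ndimage.center_of_mass(mask)
    return float(cx), float(cy)


def extract_com_trajectory(
    seq: FrameSequence,
    roi: RegionOfInterest | None = None,
    cfg: MotionConfig | None = None,
    return_areas: bool = False,
):
    """Track the motion-silhouette centroid across all consecutive frame pairs.

    The centroid of the denoised difference mask of frames (i−1, i) is
    assigned to frame i, so N frames yield N−1 samples at the video fps.
    Empty masks are handled per ``cfg.empty_mask_policy``:

    * ``carry_forward`` — repeat the last valid centroid (leading empties
      are back-filled from the first valid one);
    * ``mark_missing`` — linearly interpolate over the gap.

    If every mask is empty the subject produced no detectable motion and
    an error is raised advising threshold/texture review.
    """
    cfg = cfg or MotionConfig()
    if roi is not None:
        seq = preprocess(seq, roi, cfg)
    frames = seq.frames

    centroids: list[tuple[float, float] | None] = []
    areas = np.zeros(seq.n_frames - 1)
    for i in range(1, seq.n_frames):
        raw = frame_difference_mask(frames[i - 1], frames[i], cfg)
        clean = denoise_mask(raw, cfg)
        areas[i - 1] = int(clean.sum())
        centroids.append(_centroid(clean))

    valid = [i for i, c in enumerate(centroids) if c is not None]
    if not valid:
        raise RuntimeError(
            "no motion detected in any frame pair: the subject may be "
            "perfectly still, the threshold too high, or the silhouette "
            "untextured — review threshold and recording contrast"
        )

    xy = np.full((len(centroids), 2), np.nan)
    for i in valid:
        xy[i] = centroids[i]
    if cfg.empty_mask_policy == "carry_forward":
        xy[: valid[0]] = xy[valid[0]]  # back-fill leading empties
        for i in range(valid[0] + 1, len(centroids)):
            if np.isnan(xy[i, 0]):
                xy[i] = xy[i - 1]
    else:  # mark_missing: linear interpolation across gaps
        idx = np.arange(len(centroids))
        for col in (0, 1):
            good = ~np.isnan(xy[:, col])
            xy[:, col] = np.interp(idx, idx[good], xy[good, col])

    traj = Trajectory(x=xy[:, 0], y=xy[:, 1], rate_hz=seq.fps, units="pixel")
    if return_areas:
        return traj, areas
    return traj
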