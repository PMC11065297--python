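"""Aspiration-depth tracking from grayscale frame stacks.

Converts a recorded (or rendered) micropipette-aspiration video into a
depth-vs-time curve in micrometers.  The processing chain mirrors how
such videos are analysed by hand: crop a region of interest, find the
frame just before the zona pellucida starts to move, measure the zona
thickness and the pipette inner diameter on the first frame, track the
aspirated tongue tip frame by frame along the pipette axis, compress the
time vector to the moving clip, and convert pixels to micrometers with a
conversion factor calibrated on the known pipette inner diameter.

Geometry conventions: the pipette axis is horizontal with the lumen
opening to the right of the tip plane; pixel indices are 0-based; tip
positions are measured from the tip plane, positive into the lumen.  At
rest the zona pellucida seals the pipette mouth, so the resting tip
position approximates the zona thickness ("initial aspiration depth");
the curve handed to model fitting is baseline-subtracted so its t=0
value is the instantaneous elastic jump.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import json
from pathlib import Path

import numpy as np

__all__ = [
    "FrameStack",
    "AspirationCurve",
    "PipetteGeometry",
    "crop_roi",
    "select_start_frame",
    "measure_zona_thickness",
    "measure_pipette_inner_diameter",
    "detect_pipette",
    "track_aspirated_zona",
    "compress_time_vector",
    "to_micrometers",
    "extract_curve",
    "NoMotionError",
    "DetectionError",
    "TrackingLossError",
]

CLIP_WINDOW_S = 0.5  # analysis window after motion onset


class NoMotionError(RuntimeError):
    """No motion onset found; maps to the poor-video-quality exclusion path."""


class DetectionError(RuntimeError):
    """A required boundary (zona, pipette wall) could not be detected."""


class TrackingLossError(RuntimeError):
    """Tracking lost the tongue tip mid-clip."""

    def __init__(self, last_good_frame: int):
        super().__init__(f"tracking lost after frame {last_good_frame}")
        self.last_good_frame = last_good_frame


@dataclass
class FrameStack:
    """Ordered grayscale frames of constant shape plus pixel geometry."""

    frames: np.ndarray  # (n_frames, H, W), float in [0, 1] or uint8
    frame_rate: float
    um_per_px: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frame stack needs >= 2 frames of equal shape")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class AspirationCurve:
    """Depth-vs-time series: seconds from clip start, micrometers of
    aspirated depth (baseline-subtracted, so depths[0] is the elastic
    jump), with the measurement geometry that produced it."""

    times: np.ndarray
    depths: np.ndarray
    zona_thickness_um: float = float("nan")
    pipette_inner_diameter_um: float = float("nan")
    conversion_factor: float = float("nan")  # um per px

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.times.shape != self.depths.shape:
            raise ValueError("times and depths must have the same length")
        if self.times.size and (self.times[0] != 0 or np.any(np.diff(self.times) <= 0)):
            raise ValueError("times must start at 0 and strictly increase")


@dataclass(frozen=True)
class PipetteGeometry:
    """Pipette location found in a frame (pixel units)."""

    tip_col: int            # first lumen column (tip plane)
    lumen_top: int          # first row inside the lumen
    lumen_bottom: int       # last row inside the lumen
    inner_diameter_px: int

    @property
    def axis_row(self) -> int:
        return (self.lumen_top + self.lumen_bottom) // 2


def crop_roi(stack: FrameStack, roi: tuple[int, int, int, int]) -> FrameStack:
    """Crop every frame to ``roi = (row0, col0, height, width)``."""
    r0, c0, h, w = roi
    H, W = stack.shape
    if h <= 0 or w <= 0 or r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
        raise ValueError(f"roi {roi} empty or outside frame shape {(H, W)}")
    return replace(stack, frames=stack.frames[:, r0:r0 + h, c0:c0 + w])


def _bright_threshold(img: np.ndarray) -> float:
    img = np.asarray(img, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 0.1 * max(hi, 1e-12):
        raise DetectionError("frame has no contrast: boundaries not detectable")
    return 0.5 * (lo + hi)


def detect_pipette(frame: np.ndarray) -> PipetteGeometry:
    """Locate the horizontal pipette: two bright wall bands reaching the
    right edge of the frame; the lumen lies between their inner edges and
    the tip plane is where the walls begin."""
    frame = np.asarray(frame, dtype=float)
    thr = _bright_threshold(frame)
    H, W = frame.shape
    # wall rows: bright on average over the far-right strip, which the
    # aspirated tongue never reaches (renderer enforces the margin)
    right = frame[:, W - max(W // 8, 4):]
    wall_rows = np.where(right.mean(axis=1) > thr)[0]
    if wall_rows.size < 2:
        raise DetectionError("pipette walls not found")
    gaps = np.where(np.diff(wall_rows) > 1)[0]
    if gaps.size != 1:
        raise DetectionError(f"expected 2 wall bands, found {gaps.size + 1}")
    upper_band = wall_rows[:gaps[0] + 1]
    lower_band_start = wall_rows[gaps[0] + 1]
    lumen_top, lumen_bottom = upper_band[-1] + 1, lower_band_start - 1
    # tip plane: start of the bright wall run that reaches the right edge
    row_profile = frame[upper_band].mean(axis=0)
    bright = row_profile > thr
    col = W - 1
    while col >= 0 and bright[col]:
        col -= 1
    tip_col = col + 1
    if tip_col >= W - 1:
        raise DetectionError("pipette tip plane not found")
    return PipetteGeometry(tip_col=tip_col, lumen_top=int(lumen_top),
                           lumen_bottom=int(lumen_bottom),
                           inner_diameter_px=int(lumen_bottom - lumen_top + 1))


def measure_pipette_inner_diameter(first_frame: np.ndarray) -> int:
    """Lumen width in pixels, perpendicular to the pipette axis.

    Invariant to affine intensity rescaling of the frame (the bright
    threshold adapts to the frame's own range)."""
    return detect_pipette(first_frame).inner_diameter_px


def measure_zona_thickness(first_frame: np.ndarray, scale: float) -> float:
    """Zona pellucida thickness in micrometers.

    Measured as the width of the bright annulus crossing the pipette axis
    on the far (left) side of the oocyte, where the annulus is radial and
    unobstructed by the pipette, times the micrometer-per-pixel scale.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0 um/px")
    frame = np.asarray(first_frame, dtype=float)
    geom = detect_pipette(frame)
    thr = _bright_threshold(frame)
    r = geom.axis_row
    profile = frame[r - 1:r + 2, :geom.tip_col].mean(axis=0) > thr
    idx = np.where(profile)[0]
    if idx.size == 0:
        raise DetectionError("zona annulus not found on the pipette axis")
    # first contiguous bright run from the left = outer annulus crossing
    start = idx[0]
    end = start
    while end + 1 < profile.size and profile[end + 1]:
        end += 1
    return (end - start + 1) * scale


def _tip_position(frame: np.ndarray, geom: PipetteGeometry, thr: float) -> int:
    """Tongue-tip position (px from the tip plane) in one frame: the last
    bright column of the lumen-center band before the dark lumen."""
    band = frame[geom.lumen_top + 2:geom.lumen_bottom - 1, geom.tip_col:]
    profile = band.mean(axis=0)
    bright = np.where(profile > thr)[0]
    if bright.size == 0:
        return 0
    # require contiguity from the tip plane so stray noise is ignored
    tip = 0
    while tip < profile.size and profile[tip] > thr:
        tip += 1
    return tip


def track_aspirated_zona(stack: FrameStack, start: int = 0) -> np.ndarray:
    """Per-frame tongue-tip positions (pixels from the tip plane) from
    ``start`` on.  The pipette is located once on the start frame and the
    inner zona boundary is followed along the lumen axis thereafter."""
    if not 0 <= start < len(stack):
        raise ValueError(f"start frame {start} outside stack of {len(stack)}")
    first = np.asarray(stack.frames[start], dtype=float)
    geom = detect_pipette(first)
    thr = _bright_threshold(first)
    positions = np.empty(len(stack) - start, dtype=float)
    for i, frame in enumerate(stack.frames[start:]):
        pos = _tip_position(np.asarray(frame, dtype=float), geom, thr)
        if i > 0 and pos == 0 and positions[i - 1] > 2:
            raise TrackingLossError(last_good_frame=start + i - 1)
        positions[i] = pos
    return positions


def select_start_frame(stack: FrameStack, motion_threshold: float = 1.0) -> int:
    """Index of the frame immediately before the first frame whose
    tongue-tip displacement from the baseline exceeds ``motion_threshold``
    pixels.  Raises :class:`NoMotionError` on a static stack."""
    positions = track_aspirated_zona(stack, start=0)
    moved = np.where(np.abs(positions - positions[0]) > motion_threshold)[0]
    if moved.size == 0:
        raise NoMotionError("no tongue motion above threshold in the stack")
    return max(int(moved[0]) - 1, 0)


def compress_time_vector(positions: np.ndarray, frame_rate: float,
                         motion_threshold: float = 1.0,
                         window: float = CLIP_WINDOW_S):
    """Keep the moved frames only: drop leading static frames, clip to
    the analysis window, and emit times starting at 0 from the first
    moved frame."""
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise NoMotionError("empty position vector")
    # a static prefix is a leading plateau around the first position;
    # an already-moving clip (deviation from the very next frame on)
    # passes through unchanged
    deviation = np.abs(positions - positions[0])
    moved = np.where(deviation > motion_threshold)[0]
    if moved.size == 0:
        raise NoMotionError("no motion above threshold in the clip")
    onset = 0 if moved[0] <= 1 else int(moved[0])
    n_keep = min(positions.size - onset, int(np.floor(window * frame_rate)) + 1)
    if n_keep == 0:
        raise NoMotionError("no frames left after compression")
    kept = positions[onset:onset + n_keep]
    times = np.arange(n_keep) / frame_rate
    return times, kept


def to_micrometers(positions: np.ndarray, conversion_factor: float) -> np.ndarray:
    """Convert pixel positions to micrometers.

    ``conversion_factor`` (um/px) is the ratio of a known in-frame size
    to its pixel measurement — by default the 50-um pipette inner
    diameter over its measured pixel width."""
    if conversion_factor <= 0:
        raise ValueError("conversion factor must be > 0 um/px")
    return np.asarray(positions, dtype=float) * conversion_factor


def extract_curve(stack: FrameStack, known_inner_diameter_um: float = 50.0,
                  motion_threshold: float = 1.0,
                  window: float = CLIP_WINDOW_S) -> AspirationCurve:
    """Full chain: detect geometry, find the start frame, track the
    tongue, compress time, calibrate the scale, and baseline-subtract so
    the returned depths start at the elastic jump."""
    first = np.asarray(stack.frames[0], dtype=float)
    diameter_px = measure_pipette_inner_diameter(first)
    factor = known_inner_diameter_um / diameter_px
    zona_um = measure_zona_thickness(first, scale=factor)

    start = select_start_frame(stack, motion_threshold)
    positions = track_aspirated_zona(stack, start=start)
    baseline = positions[0]  # resting tip position ~ zona thickness
    # the start frame only sets the baseline; onset detection is already
    # done, so the moving clip is taken directly from the next frame and
    # clipped to the analysis window (slow late-creep steps fall below
    # any per-frame motion threshold and must not be re-filtered here)
    motion = positions[1:]
    if motion.size == 0:
        raise NoMotionError("no frames after the start frame")
    n_keep = min(motion.size, int(np.floor(window * stack.frame_rate)) + 1)
    kept = motion[:n_keep]
    times = np.arange(n_keep) / stack.frame_rate
    depths = to_micrometers(kept - baseline, factor)
    return AspirationCurve(times=times, depths=depths,
                           zona_thickness_um=zona_um,
                           pipette_inner_diameter_um=known_inner_diameter_um,
                           conversion_factor=factor)
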