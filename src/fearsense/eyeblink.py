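"""Remote eye-blink detection from near-infrared eye video.

Per frame, the detector chains four stages:

1. the corneal specular reflection (SR) — the bright glint of the NIR
   illuminator — is found by high-intensity binarization;
2. a square pupil-search region is anchored on each glint;
3. the pupil is coarsely localized inside the region with a 3x3 sub-block
   template matcher that scores how much darker the centre block is than its
   eight neighbours (the pupil is the locally darkest structure);
4. the pupil boundary is binarized, traced and fitted with a least-squares
   ellipse.  The frame is labelled *open* iff some glint yields a plausible
   ellipse (axis ratio, radius bounds, enough boundary points); otherwise
   *closed*.

The blinking rate is the number of open-to-closed transitions per minute,
with a short debounce so single-frame detector flicker is not counted.
Sessions where the eyes stay closed for most frames carry no usable blink
signal and can be flagged for exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.measure import EllipseModel

from .geometry import Point2D, Rect

__all__ = [
    "EyeFrame",
    "EllipseParams",
    "PupilDetection",
    "BlinkSeries",
    "BlinkRateResult",
    "EyeTrackerConfig",
    "detect_specular_reflection",
    "pupil_roi_from_sr",
    "subblock_template_match",
    "fit_pupil_ellipse",
    "classify_eye_state",
    "blink_rate",
    "exclude_closed_session",
]

OPEN, CLOSED = "open", "closed"


@dataclass(frozen=True)
class EyeFrame:
    """One 8-bit eye-camera frame with its acquisition timestamp in seconds."""

    intensity: np.ndarray
    timestamp: float

    def __post_init__(self) -> None:
        img = np.asarray(self.intensity, dtype=float)
        if img.ndim != 2 or img.size == 0:
            raise ValueError("EyeFrame requires a nonempty 2-D intensity array")
        object.__setattr__(self, "intensity", img)


@dataclass(frozen=True)
class EllipseParams:
    center: Point2D
    semi_axes: tuple[float, float]  # (major, minor)
    rotation: float  # radians


@dataclass(frozen=True)
class PupilDetection:
    """Per-frame detection outcome; ``state`` is open iff an ellipse was fitted."""

    state: str
    sr_point: Point2D | None = None
    roi: Rect | None = None
    approx_center: Point2D | None = None
    ellipse: EllipseParams | None = None

    def __post_init__(self) -> None:
        if (self.state == OPEN) != (self.ellipse is not None):
            raise ValueError("state must be 'open' exactly when an ellipse is present")


@dataclass(frozen=True)
class BlinkSeries:
    """Time-ordered open/closed labels spanning ``duration`` seconds."""

    states: tuple[str, ...]
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        bad = set(self.states) - {OPEN, CLOSED}
        if bad:
            raise ValueError(f"states must be 'open'/'closed', got {bad}")
        object.__setattr__(self, "states", tuple(self.states))

    def closed_fraction(self) -> float:
        if not self.states:
            return 0.0
        return sum(s == CLOSED for s in self.states) / len(self.states)


@dataclass(frozen=True)
class BlinkRateResult:
    blink_count: int
    rate: float  # blinks per minute
    excluded: bool


@dataclass(frozen=True)
class EyeTrackerConfig:
    """Tunable thresholds of the per-frame detector.

    ``sr_threshold_frac``: a pixel counts as glint when within this fraction
    of the top of the frame's intensity range.  ``nominal_pupil_radius`` (px)
    sets the template size (mask side = 3 radii, rounded to a multiple of 3)
    and the plausible-radius band for the ellipse fit.
    """

    sr_threshold_frac: float = 0.005
    roi_half_size: int = 48
    nominal_pupil_radius: float = 14.0
    min_boundary_points: int = 20
    axis_ratio_max: float = 3.0
    radius_bounds: tuple[float, float] = (4.0, 36.0)
    min_closed_frames: int = 2
    max_closed_fraction: float = 0.5

    @property
    def mask_side(self) -> int:
        side = int(round(3 * self.nominal_pupil_radius))
        return max(3, side - side % 3)


def detect_specular_reflection(
    frame: EyeFrame, threshold_frac: float = 0.005
) -> list[Point2D]:
    """Find up to two corneal glints by binarizing the brightest pixels.

    Pixels in the top ``threshold_frac`` of the frame's intensity range are
    grouped into connected components; the intensity-weighted centroids of the
    up-to-two largest are returned left-to-right.  A frame with no bright
    component (e.g. fully dark, or eyelid-occluded) yields an empty list.
    """
    img = frame.intensity
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return []
    thr = hi - threshold_frac * (hi - lo)
    labels = measure.label(img >= thr, connectivity=2)
    props = sorted(
        measure.regionprops(labels, intensity_image=img),
        key=lambda p: p.area,
        reverse=True,
    )
    pts = []
    for p in props[:2]:
        cy, cx = p.centroid_weighted
        pts.append(Point2D(float(cx), float(cy)))
    return sorted(pts, key=lambda p: p.x)


def pupil_roi_from_sr(
    sr: Point2D, half_size: float, frame_size: tuple[int, int]
) -> Rect:
    """Square search region of side ``2*half_size`` centred on a glint, clipped."""
    width, height = frame_size
    return Rect(
        sr.x - half_size, sr.y - half_size, sr.x + half_size, sr.y + half_size
    ).clip(width, height)


def _block_sums(img: np.ndarray, side: int) -> np.ndarray:
    """Sums of all side x side windows (valid positions), via an integral image."""
    ii = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=float)
    ii[1:, 1:] = img.cumsum(axis=0).cumsum(axis=1)
    return (
        ii[side:, side:] - ii[:-side, side:] - ii[side:, :-side] + ii[:-side, :-side]
    )


def subblock_template_match(
    roi_image: np.ndarray, mask_side: int, stride: int | None = None
) -> Point2D:
    """Coarse pupil localization with a 3x3 sub-block template.

    The mask is slid over the region on a stride grid (default stride = one
    sub-block = ``mask_side / 3``); each position is scored as

        mean(eight surrounding sub-blocks) - mean(centre sub-block)

    so a dark centre with a brighter surround scores highest.  Returns the
    centre of the centre sub-block at the best position; ties break to the
    smallest (y, x) position.  Coordinates are local to ``roi_image``.
    """
    img = np.asarray(roi_image, dtype=float)
    if mask_side % 3 != 0 or mask_side <= 0:
        raise ValueError("mask_side must be a positive multiple of 3")
    H, W = img.shape
    if H < mask_side or W < mask_side:
        raise ValueError(
            f"region {img.shape} is smaller than the {mask_side}x{mask_side} mask"
        )
    sub = mask_side // 3
    if stride is None:
        stride = sub
    mask_sums = _block_sums(img, mask_side)  # (H-mask+1, W-mask+1)
    sub_sums = _block_sums(img, sub)  # (H-sub+1, W-sub+1)

    def positions(limit: int) -> list[int]:
        pos = list(range(0, limit - mask_side + 1, stride))
        if pos[-1] != limit - mask_side:
            pos.append(limit - mask_side)  # cover the trailing edge
        return pos

    best_score = -math.inf
    best_yx: tuple[int, int] | None = None
    for y in positions(H):
        for x in positions(W):
            center = sub_sums[y + sub, x + sub]
            surround = mask_sums[y, x] - center
            score = surround / (8 * sub * sub) - center / (sub * sub)
            if score > best_score:
                best_score = score
                best_yx = (y, x)
    assert best_yx is not None
    y, x = best_yx
    return Point2D(x + 1.5 * sub, y + 1.5 * sub)


def fit_pupil_ellipse(
    roi_image: np.ndarray,
    approx_center: Point2D,
    config: EyeTrackerConfig = EyeTrackerConfig(),
) -> EllipseParams | None:
    """Refine the pupil by binarization, boundary tracing and ellipse fitting.

    The region is thresholded with Otsu's method (dark = pupil candidate); the
    dark component containing — or nearest to — the coarse centre is kept, its
    outer boundary traced, and a least-squares ellipse fitted.  Returns None
    (interpreted as a closed eye) unless the fit has at least
    ``min_boundary_points`` boundary samples, an axis ratio of at most
    ``axis_ratio_max`` and both semi-axes inside ``radius_bounds``.
    Coordinates are local to ``roi_image``.
    """
    img = np.asarray(roi_image, dtype=float)
    if img.max() <= img.min():
        return None
    mask = img < threshold_otsu(img)
    if not mask.any():
        return None
    labels = measure.label(mask, connectivity=2)
    ay, ax = int(round(approx_center.y)), int(round(approx_center.x))
    ay = min(max(ay, 0), img.shape[0] - 1)
    ax = min(max(ax, 0), img.shape[1] - 1)
    target = labels[ay, ax]
    if target == 0:
        props = measure.regionprops(labels)
        target = min(
            props,
            key=lambda p: (p.centroid[0] - approx_center.y) ** 2
            + (p.centroid[1] - approx_center.x) ** 2,
        ).label
    component = labels == target
    contours = measure.find_contours(component.astype(float), 0.5)
    if not contours:
        return None
    boundary = max(contours, key=len)  # outer boundary (glint holes are shorter)
    if len(boundary) < config.min_boundary_points:
        return None
    # EllipseModel expects (x, y); contours are (row, col).
    xy = boundary[:, ::-1]
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(xy)
        if not model:
            return None
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:  # scikit-image < 0.26
        model = EllipseModel()
        if not model.estimate(xy):
            return None
        xc, yc, a, b, theta = model.params
    major, minor = (a, b) if a >= b else (b, a)
    if minor <= 0 or major / minor > config.axis_ratio_max:
        return None
    lo, hi = config.radius_bounds
    if not (lo <= minor and major <= hi):
        return None
    center = Point2D(float(xc), float(yc))
    if not (0 <= center.x < img.shape[1] and 0 <= center.y < img.shape[0]):
        return None
    return EllipseParams(center=center, semi_axes=(float(major), float(minor)),
                         rotation=float(theta))


def classify_eye_state(
    frame: EyeFrame, config: EyeTrackerConfig = EyeTrackerConfig()
) -> PupilDetection:
    """Run the full per-frame chain: glint -> region -> template -> ellipse.

    Both detected glints (one per eye) are tried; the frame is *open* if
    either yields a successful ellipse fit, which makes the detector robust to
    unilateral glint loss.  Deterministic for a fixed frame and configuration.
    """
    frame_size = (frame.intensity.shape[1], frame.intensity.shape[0])
    for sr in detect_specular_reflection(frame, config.sr_threshold_frac):
        roi = pupil_roi_from_sr(sr, config.roi_half_size, frame_size)
        rows, cols = roi.to_slices()
        patch = frame.intensity[rows, cols]
        if patch.shape[0] < config.mask_side or patch.shape[1] < config.mask_side:
            continue
        approx_local = subblock_template_match(patch, config.mask_side)
        ellipse_local = fit_pupil_ellipse(patch, approx_local, config)
        if ellipse_local is not None:
            offset_x, offset_y = cols.start, rows.start
            ellipse = EllipseParams(
                center=Point2D(
                    ellipse_local.center.x + offset_x, ellipse_local.center.y + offset_y
                ),
                semi_axes=ellipse_local.semi_axes,
                rotation=ellipse_local.rotation,
            )
            return PupilDetection(
                state=OPEN,
                sr_point=sr,
                roi=roi,
                approx_center=Point2D(
                    approx_local.x + offset_x, approx_local.y + offset_y
                ),
                ellipse=ellipse,
            )
    return PupilDetection(state=CLOSED)


def blink_rate(
    series: BlinkSeries,
    min_closed_frames: int = 2,
    max_closed_fraction: float | None = None,
) -> BlinkRateResult:
    """Count open-to-closed transitions and scale them to blinks per minute.

    A closed run only counts as a blink when it lasts at least
    ``min_closed_frames`` frames (debouncing against single-frame detector
    flicker) and is preceded by an open frame.  A long closure counts once.
    If ``max_closed_fraction`` is given, the result's ``excluded`` flag marks
    sessions whose closed-frame fraction exceeds it.
    """
    if not series.states:
        raise ValueError("empty blink series")
    count = 0
    run_len = 0
    preceded_by_open = False
    for state in series.states:
        if state == CLOSED:
            run_len += 1
        else:
            if preceded_by_open and run_len >= min_closed_frames:
                count += 1
            run_len = 0
            preceded_by_open = True
    if preceded_by_open and run_len >= min_closed_frames:
        count += 1
    rate = count * 60.0 / series.duration
    excluded = (
        exclude_closed_session(series, max_closed_fraction)
        if max_closed_fraction is not None
        else False
    )
    return BlinkRateResult(blink_count=count, rate=rate, excluded=excluded)


def exclude_closed_session(series: BlinkSeries, max_closed_fraction: float = 0.5) -> bool:
    """True when the eyes were closed for more than ``max_closed_fraction`` of frames.

    Such sessions carry no usable blink signal (the subject kept the eyes
    shut) and are removed from the analysis.
    """
    return series.closed_fraction() > max_closed_fraction


def classify_sequence(
    frames: Sequence[EyeFrame], config: EyeTrackerConfig = EyeTrackerConfig()
) -> tuple[BlinkSeries, list[PupilDetection]]:
    """Classify every frame and assemble a BlinkSeries from the timestamps.

    The series duration is the spanned time extended by one median frame
    interval, so a sequence sampled at a uniform rate over T seconds reports
    duration T.
    """
    if not frames:
        raise ValueError("no frames supplied")
    detections = [classify_eye_state(f, config) for f in frames]
    times = np.array([f.timestamp for f in frames], dtype=float)
    if len(times) > 1:
        if np.any(np.diff(times) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        duration = float(times[-1] - times[0] + np.median(np.diff(times)))
    else:
        duration = 1.0
    series = BlinkSeries(states=tuple(d.state for d in detections), duration=duration)
    return series, detections
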