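"""Facial-temperature extraction from registered visible/thermal image pairs.

Facial feature boxes (face, eyes, nose) come from an external detector — any
callable producing a :class:`FacialFeatureSet`; the synthetic generator
supplies ground-truth features for testing.  This module then

1. refines the nose box into two nostril centroids by dark-region
   binarization (Otsu threshold within the nose box),
2. lays out five measurement regions — middle forehead, both eyes, both
   cheeks — whose placement and size scale with the inter-eye distance,
3. maps the regions into thermal-image coordinates through the fitted
   bilinear transform, and
4. averages raw 14-bit thermal counts per region and per session.

Temperatures are reported on the raw sensor-count scale (0..16383); an
optional affine count-to-degree conversion can be applied by callers but is
never implied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .geometry import BilinearTransform, Point2D, Rect, apply_transform

__all__ = [
    "ROI_NAMES",
    "FacialFeatureSet",
    "ROIConfig",
    "ROISet",
    "ThermalFrame",
    "FTSessionResult",
    "NostrilDetectionError",
    "detect_nostrils",
    "define_rois",
    "map_rois_to_thermal",
    "roi_temperature",
    "session_ft",
]

#: fixed names of the five facial measurement regions
ROI_NAMES = ("middle_forehead", "left_eye", "right_eye", "left_cheek", "right_cheek")

THERMAL_MAX_COUNT = 16383  # 14-bit sensor


class NostrilDetectionError(RuntimeError):
    """Raised when fewer than two dark nostril components are found."""


@dataclass(frozen=True)
class FacialFeatureSet:
    """Facial feature positions detected in the visible-light image."""

    face_box: Rect
    left_eye: Point2D
    right_eye: Point2D
    nose_box: Rect
    nostrils: tuple[Point2D, Point2D] | None = None
    nose_center: Point2D | None = None

    def __post_init__(self) -> None:
        if self.nose_center is None and self.nostrils is not None:
            left, right = self.nostrils
            object.__setattr__(
                self,
                "nose_center",
                Point2D((left.x + right.x) / 2.0, (left.y + right.y) / 2.0),
            )

    def resolved_nose_center(self) -> Point2D:
        if self.nose_center is not None:
            return self.nose_center
        return self.nose_box.center


@dataclass(frozen=True)
class ROIConfig:
    """Region layout relative to the inter-eye (inter-ocular) distance.

    All lengths are dimensionless fractions of the inter-eye distance, so the
    layout is invariant to image scale.  Defaults: regions 0.5 x 0.35 of the
    inter-eye distance; forehead centred 0.6 above the eye line; cheeks 0.45
    below the eye line and 0.55 either side of the nose centre.
    """

    width_frac: float = 0.5
    height_frac: float = 0.35
    forehead_rise_frac: float = 0.6
    cheek_drop_frac: float = 0.45
    cheek_lateral_frac: float = 0.55


@dataclass(frozen=True)
class ROISet:
    """The five named facial measurement rectangles."""

    rois: Mapping[str, Rect]
    empty: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        missing = [n for n in ROI_NAMES if n not in self.rois]
        if missing:
            raise ValueError(f"ROISet missing region(s): {missing}")

    def __getitem__(self, name: str) -> Rect:
        return self.rois[name]

    def items(self):
        return ((n, self.rois[n]) for n in ROI_NAMES)


@dataclass(frozen=True)
class ThermalFrame:
    """A 14-bit thermal raster (raw sensor counts, nominally 320x240)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.size == 0:
            raise ValueError("ThermalFrame requires a nonempty 2-D array")
        if not np.all(np.isfinite(counts)):
            raise ValueError("thermal counts must be finite")
        if counts.min() < 0 or counts.max() > THERMAL_MAX_COUNT:
            raise ValueError(f"thermal counts must lie in [0, {THERMAL_MAX_COUNT}]")
        object.__setattr__(self, "counts", counts)

    @property
    def height(self) -> int:
        return self.counts.shape[0]

    @property
    def width(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class FTSessionResult:
    """Session-mean thermal counts per region plus the all-regions mean."""

    per_roi_mean: Mapping[str, float]
    all_regions_mean: float


def detect_nostrils(
    visible: np.ndarray, nose_box: Rect
) -> tuple[tuple[Point2D, Point2D], Point2D]:
    """Locate both nostrils inside the nose box by dark-region binarization.

    The nose patch is thresholded with Otsu's method (dark = foreground); the
    centroids of the two largest dark components are returned left-to-right,
    with the nose centre defined as their midpoint.  Coordinates are in the
    full-image frame.
    """
    img = np.asarray(visible, dtype=float)
    box = nose_box.clip(img.shape[1], img.shape[0])
    if box.is_empty():
        raise ValueError("nose_box lies outside the image")
    rows, cols = box.to_slices()
    patch = img[rows, cols]
    if patch.size == 0 or patch.max() == patch.min():
        raise NostrilDetectionError("uniform nose patch: no dark components")
    thr = threshold_otsu(patch)
    labels = measure.label(patch < thr, connectivity=2)
    props = sorted(measure.regionprops(labels), key=lambda p: p.area, reverse=True)
    if len(props) < 2:
        raise NostrilDetectionError(
            f"found {len(props)} dark component(s) in the nose box, need 2"
        )
    pts = []
    for p in props[:2]:
        cy, cx = p.centroid
        pts.append(Point2D(float(cx) + cols.start, float(cy) + rows.start))
    left, right = sorted(pts, key=lambda p: p.x)
    center = Point2D((left.x + right.x) / 2.0, (left.y + right.y) / 2.0)
    return (left, right), center


def _centered_rect(center_x: float, center_y: float, width: float, height: float) -> Rect:
    return Rect(
        center_x - width / 2.0,
        center_y - height / 2.0,
        center_x + width / 2.0,
        center_y + height / 2.0,
    )


def define_rois(features: FacialFeatureSet, config: ROIConfig = ROIConfig()) -> ROISet:
    """Lay out the five facial regions from detected feature positions.

    Deterministic for a fixed configuration; all centres and sizes scale with
    the inter-eye distance, making the layout equivariant under uniform
    scaling and mirror-symmetric for symmetric feature sets.
    """
    le, re = features.left_eye, features.right_eye
    iod = math.hypot(re.x - le.x, re.y - le.y)
    if iod <= 1e-9:
        raise ValueError("degenerate feature set: coincident eye positions")
    w = config.width_frac * iod
    h = config.height_frac * iod
    mid_x = (le.x + re.x) / 2.0
    eye_y = (le.y + re.y) / 2.0
    nose = features.resolved_nose_center()
    rois = {
        "middle_forehead": _centered_rect(mid_x, eye_y - config.forehead_rise_frac * iod, w, h),
        "left_eye": _centered_rect(le.x, le.y, w, h),
        "right_eye": _centered_rect(re.x, re.y, w, h),
        "left_cheek": _centered_rect(
            nose.x - config.cheek_lateral_frac * iod, eye_y + config.cheek_drop_frac * iod, w, h
        ),
        "right_cheek": _centered_rect(
            nose.x + config.cheek_lateral_frac * iod, eye_y + config.cheek_drop_frac * iod, w, h
        ),
    }
    return ROISet(rois=rois)


def map_rois_to_thermal(
    rois: ROISet, t: BilinearTransform, thermal_size: tuple[int, int]
) -> ROISet:
    """Carry each region into thermal coordinates through the bilinear transform.

    Each rectangle's four corners are mapped and replaced by their axis-aligned
    bounding box, clipped to the thermal image; regions that vanish after
    clipping are flagged in ``ROISet.empty``.

    ``thermal_size`` is (width, height).
    """
    width, height = thermal_size
    mapped: dict[str, Rect] = {}
    empty: set[str] = set()
    for name, rect in rois.items():
        pts = [apply_transform(t, c) for c in rect.corners()]
        xs = [p.x for p in pts]
        ys = [p.y for p in pts]
        box = Rect(min(xs), min(ys), max(xs), max(ys)).clip(width, height)
        mapped[name] = box
        if box.is_empty():
            empty.add(name)
    if len(empty) == len(ROI_NAMES):
        raise ValueError("all regions fall outside the thermal image after mapping")
    return ROISet(rois=mapped, empty=frozenset(empty))


def roi_temperature(frame: ThermalFrame, roi: Rect) -> float:
    """Arithmetic mean of raw thermal counts within a region."""
    box = roi.clip(frame.width, frame.height)
    rows, cols = box.to_slices()
    patch = frame.counts[rows, cols]
    if patch.size == 0:
        raise ValueError("empty region of interest")
    return float(patch.mean())


def session_ft(
    frames: Sequence[ThermalFrame],
    rois_per_frame: ROISet | Sequence[ROISet],
) -> FTSessionResult:
    """Session-level facial temperature: per-region means over all frames.

    ``rois_per_frame`` is either one ROISet reused for every frame (static
    head assumption) or one per frame.  The all-regions value is the
    unweighted mean of the five per-region session means.
    """
    if len(frames) == 0:
        raise ValueError("session_ft requires at least one frame")
    if isinstance(rois_per_frame, ROISet):
        roi_seq: Sequence[ROISet] = [rois_per_frame] * len(frames)
    else:
        roi_seq = rois_per_frame
        if len(roi_seq) != len(frames):
            raise ValueError("rois_per_frame length must match frames")
    per_roi: dict[str, float] = {}
    for name in ROI_NAMES:
        vals = [
            roi_temperature(frame, rois[name])
            for frame, rois in zip(frames, roi_seq)
            if name not in rois.empty
        ]
        if not vals:
            raise ValueError(f"region {name!r} has no valid frames")
        per_roi[name] = float(np.mean(vals))
    return FTSessionResult(
        per_roi_mean=per_roi,
        all_regions_mean=float(np.mean([per_roi[n] for n in ROI_NAMES])),
    )


# ---------------------------------------------------------------------------
# Plain-text interfaces (detector-bypass feature files, session tables)

def write_features(path: str | Path, features: FacialFeatureSet) -> None:
    f = features
    ns = f.nostrils
    fields = [
        f.face_box.x0, f.face_box.y0, f.face_box.x1, f.face_box.y1,
        f.left_eye.x, f.left_eye.y, f.right_eye.x, f.right_eye.y,
        f.nose_box.x0, f.nose_box.y0, f.nose_box.x1, f.nose_box.y1,
    ]
    header = (
        "face_x0,face_y0,face_x1,face_y1,leye_x,leye_y,reye_x,reye_y,"
        "nose_x0,nose_y0,nose_x1,nose_y1"
    )
    if ns is not None:
        header += ",nl_x,nl_y,nr_x,nr_y"
        fields += [ns[0].x, ns[0].y, ns[1].x, ns[1].y]
    Path(path).write_text(header + "\n" + ",".join(repr(float(v)) for v in fields) + "\n")


def read_features(path: str | Path) -> FacialFeatureSet:
    lines = Path(path).read_text().strip().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: expected a header line and one data row")
    vals = [float(v) for v in lines[1].split(",")]
    nostrils = None
    if len(vals) >= 16:
        nostrils = (Point2D(vals[12], vals[13]), Point2D(vals[14], vals[15]))
    return FacialFeatureSet(
        face_box=Rect(*vals[0:4]),
        left_eye=Point2D(vals[4], vals[5]),
        right_eye=Point2D(vals[6], vals[7]),
        nose_box=Rect(*vals[8:12]),
        nostrils=nostrils,
    )


def write_session_table(path: str | Path, result: FTSessionResult) -> None:
    lines = ["region,mean_count"]
    for name in ROI_NAMES:
        lines.append(f"{name},{result.per_roi_mean[name]!r}")
    lines.append(f"all_regions,{result.all_regions_mean!r}")
    Path(path).write_text("\n".join(lines) + "\n")
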