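"""Visible-to-thermal camera registration with a four-point bilinear transform.

A thermal camera cannot see the visual texture needed to locate facial
features, so features are detected in a co-mounted visible-light camera and
their coordinates are carried over to the thermal image.  The mapping between
the two image planes is modelled as the 8-parameter bilinear transform

    Tx = a*Vx + b*Vy + c*Vx*Vy + d
    Ty = e*Vx + f*Vy + g*Vx*Vy + h

which is fitted from exactly four point correspondences (in practice four
near-infrared illuminators visible to both cameras).  The x- and y-coefficient
sets are two independent 4-unknown linear systems over the design rows
(Vx, Vy, Vx*Vy, 1).

Coordinates are 0-based continuous pixel centres, x rightward, y downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skimage import measure

__all__ = [
    "Point2D",
    "CorrespondencePair",
    "BilinearTransform",
    "CalibrationReport",
    "CalibrationError",
    "BlobDetectionError",
    "fit_bilinear_transform",
    "apply_transform",
    "point_error",
    "calibration_report",
    "detect_calibration_blobs",
    "read_correspondences",
    "write_correspondences",
    "read_transform",
    "write_transform",
]

#: condition-number bound above which a 4-point configuration is declared degenerate
CONDITION_LIMIT = 1e12


class CalibrationError(RuntimeError):
    """Raised when the four calibration points form a degenerate configuration."""


class BlobDetectionError(RuntimeError):
    """Raised when fewer calibration blobs are found than expected."""


@dataclass(frozen=True)
class Point2D:
    """A continuous 2-D pixel position (0-based, x rightward, y downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"Point2D coordinates must be finite, got ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in continuous pixel coordinates, [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x0, self.y0, self.x1, self.y1)):
            raise ValueError("Rect bounds must be finite")
        if self.x1 < self.x0 or self.y1 < self.y0:
            raise ValueError(f"Rect has negative extent: {self}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def center(self) -> Point2D:
        return Point2D((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def is_empty(self) -> bool:
        return self.width <= 0 or self.height <= 0

    def contains(self, p: Point2D) -> bool:
        return self.x0 <= p.x <= self.x1 and self.y0 <= p.y <= self.y1

    def corners(self) -> tuple[Point2D, Point2D, Point2D, Point2D]:
        return (
            Point2D(self.x0, self.y0),
            Point2D(self.x1, self.y0),
            Point2D(self.x1, self.y1),
            Point2D(self.x0, self.y1),
        )

    def clip(self, width: float, height: float) -> "Rect":
        """Clip to an image of the given size; may return an empty rectangle."""
        x0 = min(max(self.x0, 0.0), float(width))
        x1 = min(max(self.x1, 0.0), float(width))
        y0 = min(max(self.y0, 0.0), float(height))
        y1 = min(max(self.y1, 0.0), float(height))
        return Rect(x0, y0, x1, y1)

    def to_slices(self) -> tuple[slice, slice]:
        """Integer (row, col) slices covering the rectangle (bounds rounded)."""
        return (
            slice(int(round(self.y0)), int(round(self.y1))),
            slice(int(round(self.x0)), int(round(self.x1))),
        )


@dataclass(frozen=True)
class CorrespondencePair:
    """A matched position in the visible-light and thermal image planes."""

    visible: Point2D
    thermal: Point2D


@dataclass(frozen=True)
class BilinearTransform:
    """Coefficients of the 8-parameter bilinear image-to-image mapping."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    g: float
    h: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in self.coefficients()):
            raise ValueError("BilinearTransform coefficients must be finite")

    @classmethod
    def identity(cls) -> "BilinearTransform":
        return cls(1.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0)

    def coefficients(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.d, self.e, self.f, self.g, self.h)


@dataclass(frozen=True)
class CalibrationReport:
    """Per-point and mean registration error against manually marked ground truth."""

    per_point_error: tuple[tuple[Point2D, Point2D, float], ...]
    mean_error: float


def _design_row(p: Point2D) -> list[float]:
    return [p.x, p.y, p.x * p.y, 1.0]


def fit_bilinear_transform(pairs: Sequence[CorrespondencePair]) -> BilinearTransform:
    """Fit the bilinear transform from exactly four point correspondences.

    The x- and y-coefficient quadruples are solved as two independent 4x4
    linear systems sharing the design matrix with rows (Vx, Vy, Vx*Vy, 1).

    Raises
    ------
    ValueError
        If the number of pairs is not four.
    CalibrationError
        If the four visible points are degenerate (singular or nearly
        singular design matrix, e.g. three collinear points).
    """
    if len(pairs) != 4:
        raise ValueError(f"exactly 4 correspondence pairs are required, got {len(pairs)}")
    A = np.array([_design_row(p.visible) for p in pairs], dtype=float)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise CalibrationError(
            f"degenerate calibration configuration (condition number {cond:.3g})"
        )
    tx = np.array([p.thermal.x for p in pairs], dtype=float)
    ty = np.array([p.thermal.y for p in pairs], dtype=float)
    a, b, c, d = np.linalg.solve(A, tx)
    e, f, g, h = np.linalg.solve(A, ty)
    return BilinearTransform(a, b, c, d, e, f, g, h)


def apply_transform(t: BilinearTransform, p: Point2D) -> Point2D:
    """Map a visible-image position into thermal-image coordinates (no rounding)."""
    return Point2D(
        t.a * p.x + t.b * p.y + t.c * p.x * p.y + t.d,
        t.e * p.x + t.f * p.y + t.g * p.x * p.y + t.h,
    )


def point_error(ground_truth: Point2D, calculated: Point2D) -> float:
    """Euclidean distance in pixels between a ground-truth and a mapped position."""
    return math.hypot(calculated.x - ground_truth.x, calculated.y - ground_truth.y)


def calibration_report(
    pairs: Iterable[tuple[Point2D, Point2D]],
) -> CalibrationReport:
    """Per-point Euclidean errors and their arithmetic mean.

    ``pairs`` holds (ground truth, calculated) thermal positions for probe
    points not used in the fit.
    """
    rows = [(gt, calc, point_error(gt, calc)) for gt, calc in pairs]
    if not rows:
        raise ValueError("calibration_report requires at least one pair")
    mean = float(np.mean([r[2] for r in rows]))
    return CalibrationReport(per_point_error=tuple(rows), mean_error=mean)


def detect_calibration_blobs(
    image: np.ndarray,
    expected_count: int,
    threshold: float | None = None,
    sigma_factor: float = 3.0,
    row_tolerance: float | None = None,
) -> list[Point2D]:
    """Locate bright calibration blobs (NIR illuminator spots) in an image.

    Pixels above ``threshold`` (default: image mean + ``sigma_factor`` standard
    deviations) are grouped into 8-connected components; the intensity-weighted
    centroids of the ``expected_count`` largest components are returned in
    row-major order (top-to-bottom rows, left-to-right within a row).

    Raises
    ------
    BlobDetectionError
        If fewer components than ``expected_count`` are found.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("image must be nonempty")
    if expected_count < 1:
        raise ValueError("expected_count must be >= 1")
    if threshold is None:
        threshold = float(img.mean() + sigma_factor * img.std())
    mask = img > threshold
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels, intensity_image=img)
    if len(props) < expected_count:
        raise BlobDetectionError(
            f"found {len(props)} calibration blob(s), expected {expected_count}"
        )
    props.sort(key=lambda p: p.area, reverse=True)
    centroids = []
    for p in props[:expected_count]:
        cy, cx = p.centroid_weighted
        centroids.append(Point2D(float(cx), float(cy)))
    # Row-major ordering: group by y within a tolerance, then sort rows by x.
    if row_tolerance is None:
        row_tolerance = max(2.0, 0.05 * img.shape[0])
    centroids.sort(key=lambda p: p.y)
    rows: list[list[Point2D]] = []
    for pt in centroids:
        if rows and abs(pt.y - rows[-1][0].y) <= row_tolerance:
            rows[-1].append(pt)
        else:
            rows.append([pt])
    ordered: list[Point2D] = []
    for row in rows:
        ordered.extend(sorted(row, key=lambda p: p.x))
    return ordered


# ---------------------------------------------------------------------------
# Plain-text persistence

def write_correspondences(path: str | Path, pairs: Sequence[CorrespondencePair]) -> None:
    lines = ["vis_x,vis_y,th_x,th_y"]
    for p in pairs:
        fields = (p.visible.x, p.visible.y, p.thermal.x, p.thermal.y)
        lines.append(",".join(repr(float(v)) for v in fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_correspondences(path: str | Path) -> list[CorrespondencePair]:
    """Read calibration point pairs from delimited text (header required)."""
    text = Path(path).read_text().strip().splitlines()
    if not text or "vis_x" not in text[0]:
        raise ValueError(f"{path}: missing 'vis_x,vis_y,th_x,th_y' header line")
    pairs = []
    for line in text[1:]:
        if not line.strip():
            continue
        vx, vy, tx, ty = (float(v) for v in line.replace("\t", ",").split(","))
        pairs.append(CorrespondencePair(Point2D(vx, vy), Point2D(tx, ty)))
    return pairs


def write_transform(path: str | Path, t: BilinearTransform) -> None:
    """Persist the eight coefficients as a key-value text block."""
    names = "abcdefgh"
    Path(path).write_text(
        "".join(f"{n} = {float(v)!r}\n" for n, v in zip(names, t.coefficients()))
    )


def read_transform(path: str | Path) -> BilinearTransform:
    values: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            values[k.strip()] = float(v)
    missing = [n for n in "abcdefgh" if n not in values]
    if missing:
        raise ValueError(f"{path}: missing coefficient(s) {missing}")
    return BilinearTransform(*(values[n] for n in "abcdefgh"))
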