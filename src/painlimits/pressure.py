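"""Pressure-film image conditioning and peak-pressure extraction.

A thin piezoresistive film is wrapped over the face of the semi-sharp
contact body (14 mm x 14 mm, 2 mm edge radius).  Each recorded frame is a
dense grid of normal stresses (N/cm^2).  The film has blind spots at the
rounded corners, image noise, and pixels that belong to five different
views because the film bends over the edges (one overhead view, four
lateral ones).  This module implements the conditioning chain:

1. :func:`blur_per_view` -- 3x3 Gaussian blur, applied separately per
   view after projecting values onto the view normal;
2. :func:`interpolate_blind_spots` -- periodic cubic-spline interpolation
   of the missing values along the nested outer contours of the face;
3. :func:`calibrate_to_force` -- scaling so the frame integrates exactly
   to the simultaneously measured contact force;
4. :func:`peak_pressure` -- the space-time maximum, which is the
   pressure-based limit measurand.

Calibration runs last so that force conservation holds regardless of any
smoothing performed earlier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import convolve

from .errors import (
    CalibrationImpossibleError,
    InvalidArgumentError,
    UnderdeterminedInterpolationError,
)

#: manufacturer-recommended blur variance for the 3x3 kernel
DEFAULT_BLUR_VARIANCE = 2.0 / math.pi

#: film full-scale range in N/cm^2
FILM_RANGE = 1200.0

#: film quantization depth
FILM_BITS = 8

VIEW_LABELS = ("overhead", "lateral-N", "lateral-E", "lateral-S", "lateral-W")


@dataclass(frozen=True)
class FilmGeometry:
    """Sensel layout of the film on the semi-sharp contact face.

    ``coverage`` is False at blind spots (corner sensels that fall
    outside the film).  ``contours`` lists the sensels of each nested
    outer contour in traversal order; the blind spots all lie on
    contours.  ``projection`` holds the cosine between each sensel's
    surface normal and its view normal (1 on the flat face).
    """

    rows: int
    cols: int
    pitch_mm: float
    corner_radius_mm: float
    coverage: np.ndarray
    view_labels: np.ndarray
    projection: np.ndarray
    contours: tuple

    @property
    def sensel_area_cm2(self) -> float:
        return (self.pitch_mm / 10.0) ** 2

    @property
    def face_area_cm2(self) -> float:
        r = self.corner_radius_mm / 10.0
        w = self.rows * self.pitch_mm / 10.0
        h = self.cols * self.pitch_mm / 10.0
        return w * h - (4.0 - math.pi) * r * r


def _ring_cells(rows: int, cols: int, k: int) -> list:
    """Cells of ring ``k`` ordered clockwise from the top-left corner."""
    top, bottom, left, right = k, rows - 1 - k, k, cols - 1 - k
    if top > bottom or left > right:
        return []
    if top == bottom:
        return [(top, j) for j in range(left, right + 1)]
    if left == right:
        return [(i, left) for i in range(top, bottom + 1)]
    cells = [(top, j) for j in range(left, right + 1)]
    cells += [(i, right) for i in range(top + 1, bottom + 1)]
    cells += [(bottom, j) for j in range(right - 1, left - 1, -1)]
    cells += [(i, left) for i in range(bottom - 1, top, -1)]
    return cells


def default_film_geometry(
    pitch_mm: float = 1.0,
    side_mm: float = 14.0,
    corner_radius_mm: float = 2.0,
    lateral_bend_deg: float = 45.0,
) -> FilmGeometry:
    """Build the default film geometry for the 14 mm semi-sharp face.

    Sensels whose centers fall outside the rounded-rectangle face are
    blind spots.  The outermost sensel ring is bent over the edge radius
    and split into the four lateral views; its surface normal is tilted
    by ``lateral_bend_deg`` against the overhead direction, which sets
    the projection factor of those sensels.
    """
    n = int(round(side_mm / pitch_mm))
    coverage = np.ones((n, n), dtype=bool)
    r = corner_radius_mm
    for i in range(n):
        for j in range(n):
            y = (i + 0.5) * pitch_mm
            x = (j + 0.5) * pitch_mm
            # distance test only applies inside the corner squares
            cx = min(x, side_mm - x)
            cy = min(y, side_mm - y)
            if cx < r and cy < r and (cx - r) ** 2 + (cy - r) ** 2 > r * r:
                coverage[i, j] = False

    labels = np.full((n, n), "overhead", dtype=object)
    labels[0, :] = "lateral-N"
    labels[-1, :] = "lateral-S"
    labels[1:-1, 0] = "lateral-W"
    labels[1:-1, -1] = "lateral-E"

    projection = np.ones((n, n), dtype=float)
    bend = math.cos(math.radians(lateral_bend_deg))
    projection[labels != "overhead"] = bend

    contours = tuple(tuple(_ring_cells(n, n, k)) for k in range((n + 1) // 2))
    contours = tuple(c for c in contours if c)
    return FilmGeometry(
        rows=n,
        cols=n,
        pitch_mm=pitch_mm,
        corner_radius_mm=corner_radius_mm,
        coverage=coverage,
        view_labels=labels,
        projection=projection,
        contours=contours,
    )


@dataclass
class PressureFrame:
    """One film frame: normal stress (N/cm^2) at each sensel.

    ``coverage_mask`` is False at blind spots.  Values are non-negative
    and clipped to the film range.
    """

    grid: np.ndarray
    coverage_mask: np.ndarray
    view_labels: np.ndarray
    projection: np.ndarray
    timestamp: float
    sensel_area_cm2: float
    levels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.grid.shape != self.coverage_mask.shape:
            raise InvalidArgumentError("grid and coverage mask shapes differ")
        if np.any(self.grid < 0) or np.any(self.grid > FILM_RANGE):
            raise InvalidArgumentError(
                f"stresses must lie in [0, {FILM_RANGE}] N/cm^2"
            )

    def integral(self) -> float:
        """Frame force in N: sum of stresses times sensel area."""
        return float(self.grid.sum() * self.sensel_area_cm2)

    def copy(self) -> "PressureFrame":
        return replace(self, grid=self.grid.copy(),
                       coverage_mask=self.coverage_mask.copy())


def gaussian_kernel_3x3(variance: float = DEFAULT_BLUR_VARIANCE) -> np.ndarray:
    """Normalized 3x3 Gaussian kernel with the given variance (sensels^2)."""
    ax = np.arange(-1, 2, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * variance))
    return k / k.sum()


def blur_per_view(
    frame: PressureFrame, variance: float = DEFAULT_BLUR_VARIANCE
) -> PressureFrame:
    """Blur each view of the frame independently.

    Values are first multiplied by the projection factor of their view
    (the fraction of the stress vector the sensor records along the view
    normal), then smoothed with a 3x3 Gaussian kernel whose weights are
    renormalized over the sensels of the same view (normalized
    convolution), so constants within a view are preserved and nothing
    bleeds across view boundaries or into blind spots.  Mass is
    conserved for stress concentrated in a view's interior; the
    renormalization at view edges is not exactly mass-conserving, which
    is why force calibration runs after, not before, the blur.
    """
    if frame.view_labels is None:
        raise InvalidArgumentError("frame has no view labels")
    kernel = gaussian_kernel_3x3(variance)
    out = np.zeros_like(frame.grid)
    scaled = frame.grid * frame.projection
    for view in np.unique(frame.view_labels):
        support = (frame.view_labels == view) & frame.coverage_mask
        if not support.any():
            continue
        num = convolve(np.where(support, scaled, 0.0), kernel, mode="constant")
        den = convolve(support.astype(float), kernel, mode="constant")
        out[support] = num[support] / den[support]
    new = frame.copy()
    new.grid = np.clip(out, 0.0, FILM_RANGE)
    return new


def interpolate_blind_spots(
    frame: PressureFrame, geometry: FilmGeometry
) -> PressureFrame:
    """Fill blind spots by periodic spline interpolation along contours.

    For every nested outer contour of the face, the covered values are
    mapped over their arc-length position along the contour and the gaps
    are closed with a periodic cubic spline.  Covered sensels are
    returned unchanged.
    """
    if frame.coverage_mask.all():
        return frame.copy()
    new = frame.copy()
    for contour in geometry.contours:
        cells = list(contour)
        covered = [frame.coverage_mask[i, j] for i, j in cells]
        if all(covered):
            continue
        n_cov = sum(covered)
        if n_cov < 4:
            raise UnderdeterminedInterpolationError(
                f"contour has only {n_cov} covered sensels"
            )
        # arc-length positions of the cell centers along the closed ring
        pts = np.array(cells, dtype=float) * geometry.pitch_mm
        steps = np.linalg.norm(np.diff(pts, axis=0, append=pts[:1]), axis=1)
        t = np.concatenate(([0.0], np.cumsum(steps[:-1])))
        total = float(steps.sum())
        t_cov = t[covered]
        v_cov = np.array([frame.grid[i, j] for (i, j), c in zip(cells, covered) if c])
        x = np.concatenate((t_cov, [t_cov[0] + total]))
        y = np.concatenate((v_cov, [v_cov[0]]))
        spline = CubicSpline(x, y, bc_type="periodic")
        for (i, j), tc, c in zip(cells, t, covered):
            if not c:
                tt = tc if tc >= t_cov[0] else tc + total
                new.grid[i, j] = min(max(float(spline(tt)), 0.0), FILM_RANGE)
                new.coverage_mask[i, j] = True
    return new


def calibrate_to_force(frame: PressureFrame, contact_force: float) -> PressureFrame:
    """Scale the frame so it integrates exactly to the measured force."""
    if not frame.coverage_mask.all():
        raise InvalidArgumentError("frame must be fully covered before calibration")
    if contact_force <= 0:
        raise InvalidArgumentError("contact force must be positive")
    integral = frame.integral()
    if integral <= 0:
        raise CalibrationImpossibleError(
            "cannot calibrate a zero frame to a positive force"
        )
    new = frame.copy()
    new.grid = frame.grid * (contact_force / integral)
    return new


def peak_pressure(frames) -> float:
    """Space-time maximum stress over a processed frame stack (N/cm^2)."""
    frames = list(frames)
    if not frames:
        raise InvalidArgumentError("empty frame stack")
    return float(max(f.grid.max() for f in frames))


def process_frames(frames, forces, geometry: FilmGeometry) -> list:
    """Run the canonical chain blur -> interpolate -> calibrate per frame."""
    forces = np.asarray(forces, dtype=float)
    frames = list(frames)
    if len(frames) != forces.size:
        raise InvalidArgumentError("one force value per frame is required")
    out = []
    for frame, force in zip(frames, forces):
        f = blur_per_view(frame)
        f = interpolate_blind_spots(f, geometry)
        f = calibrate_to_force(f, float(force))
        out.append(f)
    return out
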