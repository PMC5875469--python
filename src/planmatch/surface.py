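"""Surface point clouds: contour resampling, dose sampling, isodose cropping.

The alignment and similarity metric both operate on sampled surface
points, not meshes: contours are resampled along their polylines at a
configurable arc-length spacing (2 mm default, below typical slice
spacing), and organ-at-risk clouds are restricted to the high-dose
region by keeping only points receiving at least a stated fraction
(80 % by default) of the prescription dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .dicom_io import ContourSet, DoseGrid
from .errors import EmptyCloudError

DEFAULT_MAX_POINT_SPACING = 2.0  # mm
DEFAULT_ISODOSE_FRACTION = 0.8


@dataclass
class SurfaceCloud:
    """Sampled 3D points (mm, LPS) on one structure's surface."""

    structure_name: str
    points: np.ndarray  # (N, 3)
    case_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.points.size and not np.all(np.isfinite(self.points)):
            raise ValueError("surface points must be finite")

    def __len__(self) -> int:
        return int(self.points.shape[0])

    @property
    def is_empty(self) -> bool:
        return len(self) == 0

    def translated(self, t: np.ndarray) -> "SurfaceCloud":
        return SurfaceCloud(self.structure_name, self.points + np.asarray(t, float),
                            case_id=self.case_id)


def _resample_polyline(poly: np.ndarray, spacing: float) -> np.ndarray:
    """Resample one closed polygon at arc-length intervals <= spacing.

    Original vertices are always preserved; each edge is subdivided into
    ceil(length / spacing) equal segments.
    """
    out = []
    n = poly.shape[0]
    for i in range(n):
        a = poly[i]
        b = poly[(i + 1) % n]
        length = float(np.linalg.norm(b - a))
        if length < 1e-12:
            out.append(a[None, :])
            continue
        n_seg = max(1, int(np.ceil(length / spacing - 1e-12)))
        frac = np.arange(n_seg) / n_seg
        out.append(a[None, :] + frac[:, None] * (b - a)[None, :])
    return np.concatenate(out, axis=0)


def contours_to_cloud(
    c: ContourSet,
    max_point_spacing: float = DEFAULT_MAX_POINT_SPACING,
    case_id: str = "",
) -> SurfaceCloud:
    """Convert a ContourSet to a surface point cloud.

    Each slice polygon is resampled along its perimeter at arc-length
    intervals no larger than ``max_point_spacing``; the union of all
    slice samples is returned.
    """
    if max_point_spacing <= 0:
        raise ValueError("max_point_spacing must be positive")
    if not c.slices:
        raise EmptyCloudError(f"structure {c.structure_name!r} has no contours")
    pts = np.concatenate(
        [_resample_polyline(poly, max_point_spacing) for poly in c.slices], axis=0
    )
    return SurfaceCloud(c.structure_name, pts, case_id=case_id)


def sample_dose_at_points(g: DoseGrid, pts: np.ndarray) -> np.ndarray:
    """Trilinear dose interpolation at arbitrary points (mm).

    Points outside the grid return 0 Gy — dose grids cover the treated
    region, so the outside is treated as clinically low dose.
    """
    pts = np.asarray(pts, dtype=float).reshape(-1, 3)
    interp = RegularGridInterpolator(
        g.axes(), g.values, method="linear", bounds_error=False, fill_value=0.0
    )
    return interp(pts)


def crop_by_isodose(
    cloud: SurfaceCloud, g: DoseGrid, fraction: float = DEFAULT_ISODOSE_FRACTION
) -> SurfaceCloud:
    """Restrict a cloud to points receiving >= fraction x prescription dose.

    May return an empty cloud (the caller skips such structures at
    scoring time); emptiness is a flagged condition, not an error.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("isodose fraction must be in [0, 1]")
    if g.prescription_dose is None:
        raise ValueError("dose grid has no prescription dose set")
    dose = sample_dose_at_points(g, cloud.points)
    keep = dose >= fraction * g.prescription_dose
    return SurfaceCloud(cloud.structure_name, cloud.points[keep], case_id=cloud.case_id)
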