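"""Cumulative dose-volume histograms and DVH-derived constraint suggestions.

The DVH operator rasterizes a structure's contours onto the dose grid
(voxel counting, even-odd fill rule, no sub-voxel partial volumes) and
accumulates the cumulative curve V(d) = percent of structure volume
receiving at least d Gy. Constraint suggestions are read off a stored
curve at the requested dose levels: a case's achieved V(d) becomes the
upper limit V(d) <= that value for the new plan's optimizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath

from .dicom_io import ContourSet, DoseGrid

log = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.1  # Gy


@dataclass
class DVHCurve:
    """Cumulative DVH: volume_percent[i] = % volume receiving >= dose_bins[i]."""

    structure_name: str
    dose_bins: np.ndarray  # ascending Gy edges, starting at 0
    volume_percent: np.ndarray  # same length, non-increasing, in [0, 100]
    n_voxels: int = 0
    voxel_volume_mm3: float = 0.0

    def __post_init__(self) -> None:
        self.dose_bins = np.asarray(self.dose_bins, dtype=float)
        self.volume_percent = np.asarray(self.volume_percent, dtype=float)
        if self.dose_bins.shape != self.volume_percent.shape:
            raise ValueError("dose_bins and volume_percent must have equal length")
        if np.any(np.diff(self.volume_percent) > 1e-9):
            raise ValueError("cumulative DVH must be non-increasing")

    def volume_at(self, dose: float) -> float:
        """Linear interpolation of V(dose); 0 beyond the last bin."""
        if dose > self.dose_bins[-1]:
            return 0.0
        return float(np.interp(dose, self.dose_bins, self.volume_percent))


@dataclass
class DoseVolumeConstraint:
    """Upper dose-volume constraint: V(dose) <= volume_limit %."""

    structure_name: str
    dose: float  # Gy
    volume_limit: float  # %
    kind: str = "upper"

    def __post_init__(self) -> None:
        if self.dose < 0 or not 0 <= self.volume_limit <= 100:
            raise ValueError("invalid dose-volume constraint")


def rasterize_structure(c: ContourSet, g: DoseGrid) -> np.ndarray:
    """Boolean voxel mask of a contoured structure on the dose grid.

    A voxel centre is in the mask iff it lies inside an odd number of
    polygons (even-odd rule) of the nearest contour slice; voxel planes
    farther than half a slice spacing from any contour slice are empty.
    """
    if not c.slices:
        raise ValueError("cannot rasterize an empty contour set")
    xs, ys, zs = g.axes()
    mask = np.zeros(g.shape, dtype=bool)

    slice_z = np.array(sorted({round(float(p[0, 2]), 4) for p in c.slices}))
    by_z: dict[float, list[np.ndarray]] = {}
    for poly in c.slices:
        by_z.setdefault(round(float(poly[0, 2]), 4), []).append(poly)
    if len(slice_z) > 1:
        half = float(np.median(np.diff(slice_z))) / 2.0
    else:
        half = g.spacing[2] / 2.0

    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    plane_pts = np.column_stack([gx.ravel(), gy.ravel()])
    any_hit = False
    for k, z in enumerate(zs):
        j = int(np.argmin(np.abs(slice_z - z)))
        if abs(slice_z[j] - z) > half + 1e-9:
            continue
        inside = np.zeros(plane_pts.shape[0], dtype=bool)
        for poly in by_z[float(slice_z[j])]:
            # first vertex follows the last: close explicitly so no vertex
            # is swallowed by a CLOSEPOLY code
            ring = np.vstack([poly[:, :2], poly[:1, :2]])
            path = MplPath(ring, closed=True)
            inside ^= path.contains_points(plane_pts)  # even-odd via XOR
        mask[:, :, k] = inside.reshape(len(xs), len(ys))
        any_hit = any_hit or bool(inside.any())
    if not any_hit:
        log.warning("structure %r lies entirely outside the dose grid",
                    c.structure_name)
    return mask


def compute_dvh(
    g: DoseGrid,
    mask: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    structure_name: str = "",
) -> DVHCurve:
    """Cumulative DVH over the masked voxels; V(0) = 100 exactly."""
    doses = g.values[mask]
    if doses.size == 0:
        raise ValueError("cannot compute a DVH on an empty mask")
    n_bins = int(np.ceil(doses.max() / bin_width)) + 2
    edges = bin_width * np.arange(n_bins)
    sorted_doses = np.sort(doses)
    # voxels with dose >= edge, exact at edge values
    n_ge = doses.size - np.searchsorted(sorted_doses, edges, side="left")
    volume = 100.0 * n_ge / doses.size
    voxel_vol = float(np.prod(g.spacing))
    return DVHCurve(structure_name, edges, volume,
                    n_voxels=int(doses.size), voxel_volume_mm3=voxel_vol)


def extract_constraints(
    curve: DVHCurve, doses: list[float] | tuple[float, ...]
) -> list[DoseVolumeConstraint]:
    """Read upper constraints V(d) <= achieved volume off a database DVH."""
    return [
        DoseVolumeConstraint(curve.structure_name, float(d), curve.volume_at(float(d)))
        for d in doses
    ]


def export_dvh(curve: DVHCurve, path: str | Path, delimiter: str = "\t") -> Path:
    """Write one curve as delimited text: dose (Gy), volume (%)."""
    path = Path(path)
    lines = ["dose_gy%svolume_pct" % delimiter]
    lines += [
        f"{d:.4f}{delimiter}{v:.6f}"
        for d, v in zip(curve.dose_bins, curve.volume_percent)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def export_constraints(
    constraints: list[DoseVolumeConstraint], path: str | Path, delimiter: str = "\t"
) -> Path:
    """Write constraint suggestions as a delimited block usable as optimizer input."""
    path = Path(path)
    lines = ["structure%sdose_gy%svolume_limit_pct%skind" % (delimiter, delimiter, delimiter)]
    lines += [
        f"{c.structure_name}{delimiter}{c.dose:.2f}{delimiter}{c.volume_limit:.2f}{delimiter}{c.kind}"
        for c in constraints
    ]
    path.write_text("\n".join(lines) + "\n")
    return path
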