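"""Translation-only iterative-closest-point alignment of target surfaces.

The query patient's target (prostate/PTV) cloud is registered to a
database case's target by a rigid translation only: the transform is
initialized with the difference of the centers of mass, then refined by
ICP iterations that alternate nearest-point correspondence with an
update by the mean correspondence residual. Rotation and scaling are
deliberately excluded — the prostate is roughly isotropic and the plan
is anchored by the isocenter position alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .dicom_io import PlanRecord
from .errors import EmptyCloudError
from .surface import SurfaceCloud

DEFAULT_MAX_ITER = 50
DEFAULT_TOL = 0.01  # mm, translation-update norm


@dataclass
class AlignmentResult:
    """Outcome of a translation-only ICP run.

    ``translation`` maps patient (moving) points into the database
    (fixed) frame: aligned = moving + translation.
    """

    translation: np.ndarray
    final_mean_distance: float
    n_iterations: int
    converged: bool
    mean_distance_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)


def center_of_mass(cloud: SurfaceCloud) -> np.ndarray:
    """Arithmetic mean of the cloud's points (mm)."""
    if cloud.is_empty:
        raise EmptyCloudError(f"cannot take center of mass of empty cloud "
                              f"{cloud.structure_name!r}")
    return cloud.points.mean(axis=0)


def align_translation(
    moving: SurfaceCloud,
    fixed: SurfaceCloud,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> AlignmentResult:
    """Find the translation aligning ``moving`` onto ``fixed``.

    Starts from the center-of-mass difference, then iterates: match each
    moving point to its nearest fixed point (KD-tree; equidistant ties
    resolved to the lowest fixed-point index), shift by the mean residual
    vector. A candidate update that would increase the mean closest-point
    distance is rejected and iteration stops, so the mean distance is
    non-increasing across accepted iterations. Stops when the update norm
    drops below ``tol`` (mm) or after ``max_iter`` iterations.
    """
    if moving.is_empty or fixed.is_empty:
        raise EmptyCloudError("alignment requires two nonempty clouds")
    tree = cKDTree(fixed.points)
    t = center_of_mass(fixed) - center_of_mass(moving)
    dist, _ = tree.query(moving.points + t)
    mean_dist = float(dist.mean())
    history = [mean_dist]
    converged = False
    n_iter = 0
    for _ in range(max_iter):
        n_iter += 1
        dist, idx = tree.query(moving.points + t)
        delta = (fixed.points[idx] - (moving.points + t)).mean(axis=0)
        cand = t + delta
        cand_dist, _ = tree.query(moving.points + cand)
        cand_mean = float(cand_dist.mean())
        if cand_mean > mean_dist + 1e-12:
            # mean-squared-optimal step would worsen the mean distance: stop
            converged = True
            break
        t = cand
        mean_dist = cand_mean
        history.append(mean_dist)
        if float(np.linalg.norm(delta)) < tol:
            converged = True
            break
    return AlignmentResult(t, mean_dist, max(n_iter, 1), converged, history)


def suggested_isocenter(db_plan: PlanRecord, a: AlignmentResult) -> np.ndarray:
    """Map the database plan's isocenter into the patient frame.

    The alignment translation maps patient points into the database
    frame, so the database isocenter comes back through the inverse:
    iso_patient = iso_database - translation.
    """
    return np.asarray(db_plan.isocenter, dtype=float) - a.translation
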