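"""Anatomical similarity scoring: mean closest-point surface distance.

After target alignment, a candidate case is scored by looping over all
points of the *database* case's surfaces — the target plus the
isodose-cropped bladder and rectum — recording each point's closest
distance to the corresponding patient structure, and taking the mean
over all those points. The direction (database -> patient) makes the
cropped database surface the scored object; the score is therefore
asymmetric by construction. Smaller is more similar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyCloudError
from .surface import SurfaceCloud

if TYPE_CHECKING:  # pragma: no cover
    from .alignment import AlignmentResult
    from .database import DatabaseEntry

log = logging.getLogger(__name__)

TARGET = "target"
SCORED_STRUCTURES = (TARGET, "bladder", "rectum")


@dataclass
class MatchScore:
    """Similarity of one database case to the query patient."""

    case_id: str
    pooled_mean_distance: float
    per_structure: dict[str, tuple[float, int]]  # name -> (mean mm, n_points)
    n_points_total: int
    skipped_structures: list[str] = field(default_factory=list)


def closest_distances(source: np.ndarray, target: SurfaceCloud) -> np.ndarray:
    """Euclidean distance from each source point to its nearest target point."""
    if target.is_empty:
        raise EmptyCloudError("closest_distances requires a nonempty target cloud")
    source = np.asarray(source, dtype=float).reshape(-1, 3)
    dist, _ = cKDTree(target.points).query(source)
    return dist


def score_case(
    patient: dict[str, SurfaceCloud],
    entry: "DatabaseEntry",
    alignment: "AlignmentResult",
    equal_weight: bool = False,
) -> MatchScore:
    """Score one database entry against the (aligned) patient anatomy.

    Patient clouds are mapped into the database frame by the alignment
    translation; distances run from the database entry's points (target
    uncropped, OARs isodose-cropped) to the patient's clouds. The pooled
    score is the point-count-weighted mean over all database points
    (``equal_weight=True`` averages the per-structure means instead).
    Structures missing or empty on either side are skipped and recorded.
    """
    if TARGET not in patient or patient[TARGET].is_empty:
        raise EmptyCloudError("patient has no target cloud")
    if entry.target_cloud.is_empty:
        raise EmptyCloudError(f"entry {entry.case_id} has no target cloud")
    t = alignment.translation
    db_clouds = {TARGET: entry.target_cloud, **entry.cropped_oar_clouds}

    per_structure: dict[str, tuple[float, int]] = {}
    skipped: list[str] = []
    for name in SCORED_STRUCTURES:
        db_cloud = db_clouds.get(name)
        pat_cloud = patient.get(name)
        if db_cloud is None or db_cloud.is_empty:
            if name in db_clouds or name in patient:
                log.warning("case %s: database structure %r empty/missing; skipped",
                            entry.case_id, name)
                skipped.append(name)
            continue
        if pat_cloud is None or pat_cloud.is_empty:
            log.warning("case %s: patient structure %r missing; skipped",
                        entry.case_id, name)
            skipped.append(name)
            continue
        d = closest_distances(db_cloud.points, pat_cloud.translated(t))
        per_structure[name] = (float(d.mean()), int(d.size))

    n_total = sum(n for _, n in per_structure.values())
    if equal_weight:
        pooled = float(np.mean([m for m, _ in per_structure.values()]))
    else:
        pooled = sum(m * n for m, n in per_structure.values()) / n_total
    return MatchScore(entry.case_id, float(pooled), per_structure, n_total, skipped)
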