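"""End-to-end query: filter, align, score, rank, retrieve.

For a new patient (a directory holding at least an RT Structure Set),
every database entry passing the optional criteria filter is aligned to
the patient target by translation-only ICP and scored by the mean
closest-point surface distance over the database case's high-dose
surfaces. Candidates are ranked ascending (most similar on top); the
best match's plan, suggested isocenter and DVH-derived constraint
suggestions form the retrievable payload.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom

from . import alignment as align_mod
from . import dicom_io, dvh, surface
from .alignment import AlignmentResult
from .config import Config
from .database import DatabaseEntry, SearchCriteria, filter_entries, \
    standardize_structure_names
from .dvh import DoseVolumeConstraint
from .errors import CaseRejectedError, PlanmatchError
from .similarity import TARGET, MatchScore, score_case
from .surface import SurfaceCloud

log = logging.getLogger(__name__)


@dataclass
class BestMatch:
    """Payload retrieved for the top-ranked case."""

    case_id: str
    suggested_isocenter: np.ndarray
    plan: dicom_io.PlanRecord
    constraints: list[DoseVolumeConstraint]
    dvh_curves: dict
    source_plan_path: str


@dataclass
class SearchResult:
    ranked: list[MatchScore]
    best: BestMatch | None
    n_candidates: int
    criteria_used: SearchCriteria | None
    alignments: dict[str, AlignmentResult] = field(default_factory=dict)
    patient_identity: dict = field(default_factory=dict)
    reason: str = ""


def load_patient(patient_dir: str | Path, config: Config | None = None
                 ) -> tuple[dict[str, SurfaceCloud], dict]:
    """Build the patient's structure clouds from the first RTSTRUCT found.

    Returns (clouds keyed by canonical name, patient identity dict).
    The query side needs only the segmentation — dose and plan files,
    if present, are ignored.
    """
    config = config or Config()
    patient_dir = Path(patient_dir)
    struct_path = None
    for path in sorted(patient_dir.rglob("*")):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(path), stop_before_pixels=True,
                                 specific_tags=["SOPClassUID", "PatientID",
                                                "PatientName", "FrameOfReferenceUID"])
        except Exception:  # noqa: BLE001
            continue
        if str(getattr(ds, "SOPClassUID", "")) == dicom_io.RTSTRUCT_SOP_CLASS:
            struct_path = path
            identity = {
                "id": str(getattr(ds, "PatientID", "")),
                "name": str(getattr(ds, "PatientName", "")),
                "frame_of_reference": str(getattr(ds, "FrameOfReferenceUID", "")),
            }
            break
    if struct_path is None:
        raise CaseRejectedError(f"{patient_dir}: no RT Structure Set found")
    clouds: dict[str, SurfaceCloud] = {}
    for cs in dicom_io.read_structure_set(struct_path):
        canonical = standardize_structure_names(cs.structure_name,
                                                config.synonym_table)
        if canonical != "other" and canonical not in clouds:
            clouds[canonical] = surface.contours_to_cloud(
                cs, config.max_point_spacing, case_id=identity["id"])
    if TARGET not in clouds:
        raise CaseRejectedError(f"{patient_dir}: no target (prostate/PTV) structure")
    return clouds, identity


def run_query(patient_dir: str | Path, db: list[DatabaseEntry],
              criteria: SearchCriteria | None = None,
              config: Config | None = None) -> SearchResult:
    """Rank every filtered database case against the patient anatomy."""
    config = config or Config()
    patient, identity = load_patient(patient_dir, config)
    candidates = filter_entries(db, criteria)
    if not candidates:
        return SearchResult([], None, 0, criteria, patient_identity=identity,
                            reason="no database case satisfies the search criteria")
    scores: list[MatchScore] = []
    alignments: dict[str, AlignmentResult] = {}
    for entry in candidates:
        t0 = time.perf_counter()
        a = align_mod.align_translation(patient[TARGET], entry.target_cloud,
                                        max_iter=config.icp_max_iter,
                                        tol=config.icp_tol)
        scores.append(score_case(patient, entry, a))
        alignments[entry.case_id] = a
        log.info("case %s scored %.3f mm in %.2f s", entry.case_id,
                 scores[-1].pooled_mean_distance, time.perf_counter() - t0)
    ranked = sorted(scores, key=lambda m: (m.pooled_mean_distance, m.case_id))

    best_entry = next(e for e in candidates if e.case_id == ranked[0].case_id)
    best_align = alignments[best_entry.case_id]
    constraints: list[DoseVolumeConstraint] = []
    for name, curve in sorted(best_entry.dvh_curves.items()):
        if name == TARGET:
            continue
        constraints.extend(dvh.extract_constraints(curve, config.constraint_doses))
    best = BestMatch(
        case_id=best_entry.case_id,
        suggested_isocenter=align_mod.suggested_isocenter(best_entry.plan, best_align),
        plan=best_entry.plan,
        constraints=constraints,
        dvh_curves=best_entry.dvh_curves,
        source_plan_path=best_entry.source_paths.get("plan", ""),
    )
    return SearchResult(ranked, best, len(candidates), criteria,
                        alignments=alignments, patient_identity=identity)


def write_retargeted_plan(result: SearchResult, out_file: str | Path) -> Path:
    """Write the best match's plan re-associated with the query patient.

    The suggested isocenter replaces the stored one; arcs and MLC leaf
    positions are retained untouched.
    """
    if result.best is None:
        raise PlanmatchError("empty search result: nothing to retarget")
    if not result.best.source_plan_path:
        raise PlanmatchError("best match has no source plan file on record")
    return dicom_io.retarget_plan(
        result.best.source_plan_path, out_file, result.patient_identity,
        result.best.suggested_isocenter,
    )


def ranked_table(result: SearchResult) -> str:
    """The ranked candidate list as delimited text (most similar on top)."""
    lines = ["rank\tcase_id\tpooled_mean_distance_mm\tn_points\tskipped"]
    for i, m in enumerate(result.ranked, start=1):
        lines.append(f"{i}\t{m.case_id}\t{m.pooled_mean_distance:.6f}\t"
                     f"{m.n_points_total}\t{','.join(m.skipped_structures) or '-'}")
    return "\n".join(lines) + "\n"


def explain_match(result: SearchResult, case_id: str) -> str:
    """Diagnostic report for one ranked case: per-structure distances,
    point counts, alignment translation and convergence data."""
    match = next((m for m in result.ranked if m.case_id == case_id), None)
    if match is None:
        raise PlanmatchError(f"case {case_id!r} is not in the ranked results")
    a = result.alignments.get(case_id)
    lines = [
        f"case: {case_id}",
        f"rank: {1 + [m.case_id for m in result.ranked].index(case_id)}"
        f" of {len(result.ranked)}",
        f"pooled_mean_distance_mm: {match.pooled_mean_distance:.6f}",
        f"n_points_total: {match.n_points_total}",
        "per_structure:",
    ]
    for name, (mean, n) in sorted(match.per_structure.items()):
        lines.append(f"  {name}: mean_mm={mean:.6f} n_points={n}")
    for name in match.skipped_structures:
        lines.append(f"  {name}: skipped (empty or missing)")
    if a is not None:
        t = a.translation
        lines += [
            f"alignment_translation_mm: ({t[0]:.4f}, {t[1]:.4f}, {t[2]:.4f})",
            f"alignment_iterations: {a.n_iterations}",
            f"alignment_converged: {a.converged}",
            f"alignment_final_mean_distance_mm: {a.final_mean_distance:.6f}",
        ]
    return "\n".join(lines) + "\n"
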