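"""The project-specific search database: build, filter, persist, load.

Each entry stores exactly what the retrieval metric and the plan
hand-off need — the target surface cloud, isodose-cropped OAR clouds,
DVH curves, the plan payload, and the non-anatomical index metadata
(physician, institution, boost flag, arc count, prescription, machine)
used for criteria filtering. CT images are never stored: the metric
touches only contours and dose.

Persistence is one JSON archive per database with an explicit schema
version; Python's float <-> decimal-string round-trip is exact, so the
archive is lossless and byte-deterministic.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pydicom

from . import dicom_io, dvh, surface
from .config import Config
from .dicom_io import ArcBeam, DoseGrid, PlanRecord
from .dvh import DVHCurve
from .errors import CaseRejectedError, IntegrityError
from .similarity import TARGET
from .surface import SurfaceCloud

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# structure-name standardization
# ---------------------------------------------------------------------------


def _load_synonyms(path: str | Path | None = None) -> list[tuple[str, str]]:
    if path is None:
        text = (resources.files("planmatch") / "data/structure_synonyms.tsv").read_text()
    else:
        text = Path(path).read_text()
    rules = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, canonical = line.split("\t")
        rules.append((_normalize(key), canonical.strip()))
    # longest prefix first so e.g. "prostate" beats "prost"
    rules.sort(key=lambda kv: -len(kv[0]))
    return rules


def _normalize(name: str) -> str:
    return re.sub(r"[^a-z]", "", name.lower())


_DEFAULT_RULES = None


def standardize_structure_names(
    raw: str, synonym_table: str | Path | None = None
) -> str:
    """Map an institution's ROI name to {target, bladder, rectum, other}.

    Case-insensitive; punctuation, spaces and digits are ignored
    ("Bladder_full" -> bladder, "PTV 78" -> target). Unmapped names
    return "other".
    """
    global _DEFAULT_RULES
    if synonym_table is None:
        if _DEFAULT_RULES is None:
            _DEFAULT_RULES = _load_synonyms(None)
        rules = _DEFAULT_RULES
    else:
        rules = _load_synonyms(synonym_table)
    norm = _normalize(raw)
    for key, canonical in rules:
        if norm.startswith(key):
            return canonical
    return "other"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DatabaseEntry:
    """One preprocessed case: clouds, DVHs, plan payload, index metadata."""

    case_id: str
    target_cloud: SurfaceCloud
    cropped_oar_clouds: dict[str, SurfaceCloud]
    dvh_curves: dict[str, DVHCurve]
    plan: PlanRecord
    index_meta: dict
    source_paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.target_cloud.is_empty:
            raise ValueError("database entry requires a nonempty target cloud")
        if self.index_meta.get("n_arcs") != self.plan.n_arcs:
            raise ValueError("index n_arcs inconsistent with the plan")


@dataclass
class SearchCriteria:
    """Optional conjunctive filters on the index metadata.

    Categorical fields filter by equality; prescription dose and arc
    count by inclusive ranges. Empty criteria match everything.
    """

    physician: str | None = None
    institution: str | None = None
    machine: str | None = None
    boost_flag: bool | None = None
    n_arcs_min: int | None = None
    n_arcs_max: int | None = None
    rx_min: float | None = None
    rx_max: float | None = None

    def matches(self, meta: dict) -> bool:
        for key in ("physician", "institution", "machine", "boost_flag"):
            want = getattr(self, key)
            if want is not None and meta.get(key) != want:
                return False
        n = meta.get("n_arcs")
        if self.n_arcs_min is not None and n < self.n_arcs_min:
            return False
        if self.n_arcs_max is not None and n > self.n_arcs_max:
            return False
        rx = meta.get("prescription_dose")
        if self.rx_min is not None and rx < self.rx_min:
            return False
        if self.rx_max is not None and rx > self.rx_max:
            return False
        return True


# ---------------------------------------------------------------------------
# case ingestion
# ---------------------------------------------------------------------------

_RT_SOP_CLASSES = {
    dicom_io.RTSTRUCT_SOP_CLASS: "structures",
    dicom_io.RTDOSE_SOP_CLASS: "dose",
    dicom_io.RTPLAN_SOP_CLASS: "plan",
}


def discover_case_files(case_dir: str | Path) -> dict[str, Path]:
    """Find the one RTSTRUCT + RTDOSE + RTPLAN triple of a case directory.

    Implements the cleaning step as file filters: non-DICOM files and
    other modalities (CT series, MR scans, QA objects...) are ignored.
    Zero or multiple files of one kind reject the case by name.
    """
    case_dir = Path(case_dir)
    found: dict[str, list[Path]] = {v: [] for v in _RT_SOP_CLASSES.values()}
    for path in sorted(case_dir.rglob("*")):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(path), stop_before_pixels=True,
                                 specific_tags=["SOPClassUID", "Modality"])
        except Exception:  # noqa: BLE001 - not DICOM, filtered out
            continue
        kind = _RT_SOP_CLASSES.get(str(getattr(ds, "SOPClassUID", "")))
        if kind is None:
            log.info("cleaning filter: ignoring %s (modality %s)",
                     path.name, getattr(ds, "Modality", "?"))
            continue
        found[kind].append(path)
    out = {}
    for kind, paths in found.items():
        if len(paths) == 0:
            raise CaseRejectedError(f"{case_dir}: no RT {kind} file found")
        if len(paths) > 1:
            raise CaseRejectedError(
                f"{case_dir}: ambiguous RT {kind} files: "
                + ", ".join(p.name for p in paths)
            )
        out[kind] = paths[0]
    return out


def build_entry(case_dir: str | Path, config: Config | None = None) -> DatabaseEntry:
    """Read one case directory into a DatabaseEntry.

    Reads the RT files, standardizes structure names, builds the target
    cloud (uncropped) and the bladder/rectum clouds cropped at the
    configured isodose fraction, computes per-structure DVHs, and
    extracts the index metadata from the plan.
    """
    config = config or Config()
    files = discover_case_files(case_dir)
    plan = dicom_io.read_plan(files["plan"])
    grid = dicom_io.read_dose(files["dose"], prescription_dose=plan.prescription_dose)
    contour_sets = dicom_io.read_structure_set(files["structures"])

    case_id = plan.case_id or Path(case_dir).name
    by_canonical: dict[str, dicom_io.ContourSet] = {}
    for cs in contour_sets:
        canonical = standardize_structure_names(cs.structure_name, config.synonym_table)
        if canonical != "other" and canonical not in by_canonical:
            by_canonical[canonical] = cs
    if TARGET not in by_canonical:
        raise CaseRejectedError(f"{case_dir}: no target (prostate/PTV) structure")

    clouds = {
        name: surface.contours_to_cloud(cs, config.max_point_spacing, case_id=case_id)
        for name, cs in by_canonical.items()
    }
    cropped: dict[str, SurfaceCloud] = {}
    for name, cloud in clouds.items():
        if name == TARGET:
            continue
        cropped[name] = surface.crop_by_isodose(cloud, grid, config.isodose_fraction)
        if cropped[name].is_empty:
            log.warning("case %s: %s empty after %.0f%% isodose crop",
                        case_id, name, 100 * config.isodose_fraction)

    curves = {}
    for name, cs in by_canonical.items():
        mask = dvh.rasterize_structure(cs, grid)
        if mask.any():
            curves[name] = dvh.compute_dvh(grid, mask, config.dvh_bin_width,
                                           structure_name=name)

    index_meta = dict(plan.metadata)
    index_meta["prescription_dose"] = plan.prescription_dose
    return DatabaseEntry(
        case_id=case_id,
        target_cloud=clouds[TARGET],
        cropped_oar_clouds=cropped,
        dvh_curves=curves,
        plan=plan,
        index_meta=index_meta,
        source_paths={k: str(v) for k, v in files.items()},
    )


def filter_entries(
    entries: list[DatabaseEntry], criteria: SearchCriteria | None
) -> list[DatabaseEntry]:
    """Subset of entries satisfying every provided filter (conjunction)."""
    if criteria is None:
        return list(entries)
    return [e for e in entries if criteria.matches(e.index_meta)]


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def _cloud_to_json(c: SurfaceCloud) -> dict:
    return {"structure_name": c.structure_name, "case_id": c.case_id,
            "points": c.points.tolist()}


def _cloud_from_json(d: dict) -> SurfaceCloud:
    return SurfaceCloud(d["structure_name"], np.asarray(d["points"]).reshape(-1, 3),
                        case_id=d["case_id"])


def _curve_to_json(c: DVHCurve) -> dict:
    return {"structure_name": c.structure_name, "dose_bins": c.dose_bins.tolist(),
            "volume_percent": c.volume_percent.tolist(),
            "n_voxels": c.n_voxels, "voxel_volume_mm3": c.voxel_volume_mm3}


def _curve_from_json(d: dict) -> DVHCurve:
    return DVHCurve(d["structure_name"], d["dose_bins"], d["volume_percent"],
                    n_voxels=d["n_voxels"], voxel_volume_mm3=d["voxel_volume_mm3"])


def _plan_to_json(p: PlanRecord) -> dict:
    return {
        "case_id": p.case_id,
        "isocenter": p.isocenter.tolist(),
        "prescription_dose": p.prescription_dose,
        "metadata": p.metadata,
        "arcs": [
            {"gantry_start": a.gantry_start, "gantry_stop": a.gantry_stop,
             "rotation_direction": a.rotation_direction, "collimator": a.collimator,
             "mlc": a.mlc.tolist(), "meterset": a.meterset.tolist()}
            for a in p.arcs
        ],
    }


def _plan_from_json(d: dict) -> PlanRecord:
    arcs = [ArcBeam(a["gantry_start"], a["gantry_stop"], a["rotation_direction"],
                    a["collimator"], np.asarray(a["mlc"]), np.asarray(a["meterset"]))
            for a in d["arcs"]]
    return PlanRecord(d["case_id"], d["isocenter"], arcs,
                      d["prescription_dose"], d["metadata"])


def save_database(entries: list[DatabaseEntry], path: str | Path) -> Path:
    """Persist entries to one JSON archive (schema-versioned, lossless)."""
    doc = {
        "format": "planmatch-db",
        "schema_version": SCHEMA_VERSION,
        "entries": [
            {
                "case_id": e.case_id,
                "target_cloud": _cloud_to_json(e.target_cloud),
                "cropped_oar_clouds": {k: _cloud_to_json(v)
                                       for k, v in sorted(e.cropped_oar_clouds.items())},
                "dvh_curves": {k: _curve_to_json(v)
                               for k, v in sorted(e.dvh_curves.items())},
                "plan": _plan_to_json(e.plan),
                "index_meta": e.index_meta,
                "source_paths": e.source_paths,
            }
            for e in entries
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(doc, sort_keys=True))
    return path


def load_database(path: str | Path) -> list[DatabaseEntry]:
    """Load a database archive written by :func:`save_database`."""
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise IntegrityError(f"{path}: corrupted database archive ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != "planmatch-db":
        raise IntegrityError(f"{path}: not a planmatch database archive")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise IntegrityError(
            f"{path}: schema version {doc.get('schema_version')} "
            f"incompatible with reader version {SCHEMA_VERSION}"
        )
    entries = []
    for e in doc["entries"]:
        entries.append(DatabaseEntry(
            case_id=e["case_id"],
            target_cloud=_cloud_from_json(e["target_cloud"]),
            cropped_oar_clouds={k: _cloud_from_json(v)
                                for k, v in e["cropped_oar_clouds"].items()},
            dvh_curves={k: _curve_from_json(v) for k, v in e["dvh_curves"].items()},
            plan=_plan_from_json(e["plan"]),
            index_meta=e["index_meta"],
            source_paths=e["source_paths"],
        ))
    return entries


def index_summary(entries: list[DatabaseEntry]) -> str:
    """Human-readable index: one row per case (id, metadata, point counts)."""
    header = ("case_id\tphysician\tinstitution\tmachine\tboost\tn_arcs\t"
              "rx_gy\tn_target_pts\tn_oar_pts")
    rows = [header]
    for e in entries:
        m = e.index_meta
        n_oar = sum(len(c) for c in e.cropped_oar_clouds.values())
        rows.append(
            f"{e.case_id}\t{m.get('physician', '')}\t{m.get('institution', '')}\t"
            f"{m.get('machine', '')}\t{m.get('boost_flag', '')}\t{m.get('n_arcs', '')}\t"
            f"{m.get('prescription_dose', '')}\t{len(e.target_cloud)}\t{n_oar}"
        )
    return "\n".join(rows) + "\n"
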