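"""Read and write DICOM-RT objects (RT Structure Set, RT Dose, RT Plan).

All geometry is expressed in DICOM patient coordinates (LPS: x left,
y posterior, z superior), in millimetres; dose is in Gy after grid
scaling. Dose grids are required to be axis-aligned (identity
orientation) — non-axis-aligned exports are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import FormatError

log = logging.getLogger(__name__)

RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"

#: root used for deterministically generated UIDs (synthetic data)
_UID_PREFIX = "1.2.826.0.1.3680043.10.1358."


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ContourSet:
    """All axial contours of one structure.

    ``slices`` is a list of closed planar polygons; each polygon is an
    (n, 3) float array of vertices in mm (LPS) sharing one z coordinate.
    The first vertex is treated as following the last (closed polygon).
    """

    structure_name: str
    slices: list[np.ndarray]
    frame_of_reference: str = ""

    def __post_init__(self) -> None:
        self.slices = [np.asarray(s, dtype=float) for s in self.slices]
        for poly in self.slices:
            if poly.ndim != 2 or poly.shape[1] != 3 or poly.shape[0] < 3:
                raise ValueError("each contour slice must be an (n>=3, 3) array")
            if np.ptp(poly[:, 2]) > 1e-6:
                raise ValueError("contour slice vertices must share one z coordinate")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def all_points(self) -> np.ndarray:
        return np.concatenate(self.slices, axis=0)


@dataclass
class DoseGrid:
    """Axis-aligned regular 3D dose grid.

    ``values[i, j, k]`` is the dose in Gy at
    ``origin + (i * spacing[0], j * spacing[1], k * spacing[2])``.
    ``prescription_dose`` is populated from the RT Plan by the pipeline
    (RT Dose files do not carry it) and normalizes isodose fractions.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    prescription_dose: float | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("dose grid must be 3D")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if np.any(self.values < 0):
            raise ValueError("dose values must be nonnegative")
        if self.prescription_dose is not None and self.prescription_dose <= 0:
            raise ValueError("prescription dose must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates along x, y, z in mm."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )  # type: ignore[return-value]


@dataclass
class ArcBeam:
    """One (arc) beam: gantry trajectory, MLC control points, meterset."""

    gantry_start: float
    gantry_stop: float
    rotation_direction: str  # "CW", "CC" or "NONE" (static)
    collimator: float
    mlc: np.ndarray  # (n_control_points, n_leaves) leaf positions, mm
    meterset: np.ndarray  # (n_control_points,) cumulative fraction in [0, 1]

    def __post_init__(self) -> None:
        self.mlc = np.asarray(self.mlc, dtype=float)
        self.meterset = np.asarray(self.meterset, dtype=float)
        if self.mlc.shape[0] != self.meterset.shape[0]:
            raise ValueError("one meterset weight per control point required")
        if np.any(np.diff(self.meterset) < -1e-9):
            raise ValueError("cumulative meterset must be nondecreasing")

    @property
    def n_control_points(self) -> int:
        return int(self.mlc.shape[0])


@dataclass
class PlanRecord:
    """The retrievable payload of a case: arcs, isocenter, prescription, metadata."""

    case_id: str
    isocenter: np.ndarray
    arcs: list[ArcBeam]
    prescription_dose: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.isocenter = np.asarray(self.isocenter, dtype=float)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _read_checked(path: str | Path, sop_class: str, what: str) -> pydicom.Dataset:
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # noqa: BLE001 - any parse failure is a format error
        raise FormatError(f"{path}: not a readable DICOM file ({exc})") from exc
    if getattr(ds, "SOPClassUID", None) != sop_class:
        raise FormatError(
            f"{path}: expected {what} (SOP class {sop_class}), "
            f"got modality {getattr(ds, 'Modality', 'unknown')}"
        )
    return ds


def read_structure_set(path: str | Path) -> list[ContourSet]:
    """Read an RT Structure Set into one :class:`ContourSet` per contoured ROI.

    ROI names are passed through verbatim; standardization is a separate
    step (:func:`planmatch.database.standardize_structure_names`). ROIs
    without contour data are skipped with a warning.
    """
    ds = _read_checked(path, RTSTRUCT_SOP_CLASS, "RT Structure Set")
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    frames = {
        int(r.ROINumber): str(getattr(r, "ReferencedFrameOfReferenceUID", ""))
        for r in ds.StructureSetROISequence
    }
    out: list[ContourSet] = []
    for roi in ds.ROIContourSequence:
        num = int(roi.ReferencedROINumber)
        name = names.get(num, f"ROI_{num}")
        contours = getattr(roi, "ContourSequence", None)
        if not contours:
            log.warning("ROI %r has no contour data; skipped", name)
            continue
        slices = []
        for c in contours:
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            slices.append(pts)
        out.append(ContourSet(name, slices, frame_of_reference=frames.get(num, "")))
    return out


def read_dose(path: str | Path, prescription_dose: float | None = None) -> DoseGrid:
    """Read an RT Dose file into a :class:`DoseGrid` (values in Gy)."""
    ds = _read_checked(path, RTDOSE_SOP_CLASS, "RT Dose")
    if "DoseGridScaling" not in ds:
        raise FormatError(f"{path}: RT Dose lacks DoseGridScaling")
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    if n_frames < 2 or "GridFrameOffsetVector" not in ds:
        raise FormatError(f"{path}: dose grid is not a 3D multi-frame grid")
    orient = np.asarray(getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), float)
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise FormatError(f"{path}: only axis-aligned (identity orientation) dose grids are supported")
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = np.diff(offsets)
    if np.any(dz <= 0) or np.ptp(dz) > 1e-6:
        raise FormatError(f"{path}: GridFrameOffsetVector must be uniformly ascending")
    scaling = float(ds.DoseGridScaling)
    raw = ds.pixel_array  # (frames, rows, cols) = (z, y, x)
    values = (raw.astype(np.float64) * scaling).transpose(2, 1, 0)  # -> (x, y, z)
    origin = np.asarray(ds.ImagePositionPatient, dtype=float) + np.array([0, 0, offsets[0]])
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    spacing = np.array([col_sp, row_sp, float(dz[0])])
    return DoseGrid(origin, spacing, values, prescription_dose=prescription_dose)


def read_plan(path: str | Path) -> PlanRecord:
    """Read an RT Plan (arcs, MLC control points, isocenter, prescription)."""
    ds = _read_checked(path, RTPLAN_SOP_CLASS, "RT Plan")
    beams = getattr(ds, "BeamSequence", None)
    if not beams:
        raise FormatError(f"{path}: RT Plan has no beam sequence")
    arcs: list[ArcBeam] = []
    isocenter = None
    machine = ""
    for beam in beams:
        cps = beam.ControlPointSequence
        final_w = float(getattr(beam, "FinalCumulativeMetersetWeight", 1.0)) or 1.0
        machine = str(getattr(beam, "TreatmentMachineName", machine))
        gantry = float(cps[0].GantryAngle)
        rot = str(getattr(cps[0], "GantryRotationDirection", "NONE"))
        if rot in ("", "NONE"):
            rot = "NONE"
            log.warning("beam %s is static (no gantry rotation); read anyway",
                        getattr(beam, "BeamName", "?"))
        coll = float(getattr(cps[0], "BeamLimitingDeviceAngle", 0.0))
        if isocenter is None and "IsocenterPosition" in cps[0]:
            isocenter = np.asarray(cps[0].IsocenterPosition, dtype=float)
        mlc_rows, weights = [], []
        gantry_stop = gantry
        for cp in cps:
            if "GantryAngle" in cp:
                gantry_stop = float(cp.GantryAngle)
            weights.append(float(cp.CumulativeMetersetWeight) / final_w)
            for bld in getattr(cp, "BeamLimitingDevicePositionSequence", []):
                if bld.RTBeamLimitingDeviceType in ("MLCX", "MLCY"):
                    mlc_rows.append(np.asarray(bld.LeafJawPositions, dtype=float))
        if len(mlc_rows) != len(cps):
            raise FormatError(f"{path}: MLC positions missing on some control points")
        arcs.append(ArcBeam(gantry, gantry_stop, rot, coll,
                            np.vstack(mlc_rows), np.asarray(weights)))
    if isocenter is None:
        raise FormatError(f"{path}: no isocenter in any control point")
    rx = None
    for ref in getattr(ds, "DoseReferenceSequence", []):
        if "TargetPrescriptionDose" in ref:
            rx = float(ref.TargetPrescriptionDose)
    if rx is None:
        raise FormatError(f"{path}: no target prescription dose")
    label = str(getattr(ds, "RTPlanLabel", ""))
    metadata = {
        "physician": str(getattr(ds, "ReferringPhysicianName", "")),
        "institution": str(getattr(ds, "InstitutionName", "")),
        "boost_flag": "BOOST" in label.upper(),
        "n_arcs": len(arcs),
        "machine": machine,
    }
    return PlanRecord(str(getattr(ds, "PatientID", "")), isocenter, arcs, rx, metadata)


# ---------------------------------------------------------------------------
# plan retargeting
# ---------------------------------------------------------------------------


def retarget_plan(
    source_file: str | Path,
    out_file: str | Path,
    new_patient: dict,
    new_isocenter,
) -> Path:
    """Re-associate a stored RT Plan with a new patient.

    Patient identity, frame of reference and instance identifiers are
    replaced and the isocenter moved to ``new_isocenter`` in every beam;
    arc geometry and every MLC leaf position are retained untouched.
    ``new_patient`` must provide ``id``, ``name`` and ``frame_of_reference``.
    """
    ds = _read_checked(source_file, RTPLAN_SOP_CLASS, "RT Plan")
    ds.PatientID = str(new_patient["id"])
    ds.PatientName = str(new_patient["name"])
    ds.FrameOfReferenceUID = str(new_patient["frame_of_reference"])
    ds.SOPInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    iso = [float(v) for v in np.asarray(new_isocenter, dtype=float)]
    for beam in ds.BeamSequence:
        for cp in beam.ControlPointSequence:
            if "IsocenterPosition" in cp:
                cp.IsocenterPosition = iso
    out_file = Path(out_file)
    ds.save_as(str(out_file), enforce_file_format=True)
    return out_file


# ---------------------------------------------------------------------------
# writing (used by the synthetic generator; completes the round-trip contract)
# ---------------------------------------------------------------------------


def _fmt(v: float) -> str:
    # DS values are limited to 16 bytes; 6 decimals keeps round-trip error
    # below 5e-7 mm while staying within the limit for pelvic coordinates.
    return f"{v:.6f}"


def _base_dataset(sop_class: str, sop_uid: str, case_id: str, modality: str,
                  frame_uid: str, meta: dict | None = None) -> Dataset:
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = sop_class
    file_meta.MediaStorageSOPInstanceUID = sop_uid
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_uid
    ds.Modality = modality
    ds.PatientID = case_id
    ds.PatientName = (meta or {}).get("patient_name", case_id)
    ds.StudyInstanceUID = generate_uid(_UID_PREFIX, entropy_srcs=[case_id, "study"])
    ds.SeriesInstanceUID = generate_uid(_UID_PREFIX, entropy_srcs=[case_id, modality, "series"])
    ds.FrameOfReferenceUID = frame_uid
    ds.ReferringPhysicianName = (meta or {}).get("physician", "")
    ds.InstitutionName = (meta or {}).get("institution", "")
    ds.StudyDate = "20140306"
    ds.StudyTime = "000000"
    return ds


def write_structure_set(path: str | Path, case_id: str,
                        contour_sets: list[ContourSet],
                        frame_uid: str | None = None,
                        meta: dict | None = None) -> Path:
    """Write ContourSets to a standards-compliant RT Structure Set file."""
    frame_uid = frame_uid or generate_uid(_UID_PREFIX, entropy_srcs=[case_id, "frame"])
    sop_uid = generate_uid(_UID_PREFIX, entropy_srcs=[case_id, "rtstruct"])
    ds = _base_dataset(RTSTRUCT_SOP_CLASS, sop_uid, case_id, "RTSTRUCT", frame_uid, meta)
    ds.StructureSetLabel = "planmatch"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    ds.RTROIObservationsSequence = []
    for i, cs in enumerate(contour_sets, start=1):
        roi = Dataset()
        roi.ROINumber = i
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIName = cs.structure_name
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = i
        rc.ContourSequence = []
        for poly in cs.slices:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = int(poly.shape[0])
            c.ContourData = [_fmt(v) for v in poly.reshape(-1)]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
        obs = Dataset()
        obs.ObservationNumber = i
        obs.ReferencedROINumber = i
        obs.RTROIInterpretedType = "ORGAN"
        ds.RTROIObservationsSequence.append(obs)
    path = Path(path)
    ds.save_as(str(path), enforce_file_format=True)
    return path


#: fixed dose quantization (Gy per stored integer) — keeps files deterministic
#: across platforms and round-trip error two orders below the 1e-6 Gy contract
DOSE_SCALING = 1e-7


def write_dose(path: str | Path, case_id: str, grid: DoseGrid,
               frame_uid: str | None = None, meta: dict | None = None) -> Path:
    """Write a DoseGrid to an RT Dose file (uint32 pixels, fixed scaling)."""
    frame_uid = frame_uid or generate_uid(_UID_PREFIX, entropy_srcs=[case_id, "frame"])
    sop_uid = generate_uid(_UID_PREFIX, entropy_srcs=[case_id, "rtdose"])
    ds = _base_dataset(RTDOSE_SOP_CLASS, sop_uid, case_id, "RTDOSE", frame_uid, meta)
    nx, ny, nz = grid.shape
    stored = np.round(grid.values / DOSE_SCALING).astype("<u4")
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.ImagePositionPatient = [_fmt(v) for v in grid.origin]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [_fmt(grid.spacing[1]), _fmt(grid.spacing[0])]
    ds.GridFrameOffsetVector = [_fmt(grid.spacing[2] * k) for k in range(nz)]
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = DOSE_SCALING
    ds.PixelData = stored.transpose(2, 1, 0).tobytes()
    path = Path(path)
    ds.save_as(str(path), enforce_file_format=True)
    return path


def write_plan(path: str | Path, plan: PlanRecord,
               leaf_boundaries: np.ndarray,
               frame_uid: str | None = None) -> Path:
    """Write a PlanRecord to an RT Plan file.

    ``leaf_boundaries`` are the MLC leaf-pair edge positions (n_pairs + 1
    values, mm); each arc's leaf array holds bank A then bank B positions.
    """
    case_id = plan.case_id
    frame_uid = frame_uid or generate_uid(_UID_PREFIX, entropy_srcs=[case_id, "frame"])
    sop_uid = generate_uid(_UID_PREFIX, entropy_srcs=[case_id, "rtplan"])
    meta = dict(plan.metadata)
    ds = _base_dataset(RTPLAN_SOP_CLASS, sop_uid, case_id, "RTPLAN", frame_uid, meta)
    ds.RTPlanLabel = ("BOOST " if meta.get("boost_flag") else "") + "VMAT"
    ds.RTPlanGeometry = "PATIENT"
    ds.RTPlanDate = "20140306"
    ds.RTPlanTime = "000000"

    ref = Dataset()
    ref.DoseReferenceNumber = 1
    ref.DoseReferenceStructureType = "SITE"
    ref.DoseReferenceType = "TARGET"
    ref.TargetPrescriptionDose = _fmt(plan.prescription_dose)
    ds.DoseReferenceSequence = [ref]

    n_pairs = len(leaf_boundaries) - 1
    ds.BeamSequence = []
    fg_refs = []
    for b, arc in enumerate(plan.arcs, start=1):
        beam = Dataset()
        beam.BeamNumber = b
        beam.BeamName = f"Arc{b}"
        beam.BeamType = "DYNAMIC" if arc.rotation_direction != "NONE" else "STATIC"
        beam.RadiationType = "PHOTON"
        beam.TreatmentMachineName = meta.get("machine", "")
        beam.TreatmentDeliveryType = "TREATMENT"
        beam.PrimaryDosimeterUnit = "MU"
        beam.SourceAxisDistance = "1000"
        beam.NumberOfWedges = 0
        beam.NumberOfCompensators = 0
        beam.NumberOfBoli = 0
        beam.NumberOfBlocks = 0
        beam.FinalCumulativeMetersetWeight = "1.0"
        beam.NumberOfControlPoints = arc.n_control_points

        mlc_dev = Dataset()
        mlc_dev.RTBeamLimitingDeviceType = "MLCX"
        mlc_dev.NumberOfLeafJawPairs = n_pairs
        mlc_dev.LeafPositionBoundaries = [_fmt(v) for v in leaf_boundaries]
        jaw_x = Dataset()
        jaw_x.RTBeamLimitingDeviceType = "X"
        jaw_x.NumberOfLeafJawPairs = 1
        jaw_y = Dataset()
        jaw_y.RTBeamLimitingDeviceType = "Y"
        jaw_y.NumberOfLeafJawPairs = 1
        beam.BeamLimitingDeviceSequence = [jaw_x, jaw_y, mlc_dev]

        n_cp = arc.n_control_points
        gantry = np.linspace(arc.gantry_start, arc.gantry_stop, n_cp) % 360.0
        if arc.rotation_direction == "CC":
            # counter-clockwise: angle decreases modulo 360
            span = (arc.gantry_start - arc.gantry_stop) % 360.0
            gantry = (arc.gantry_start - np.linspace(0.0, span, n_cp)) % 360.0
        elif arc.rotation_direction == "CW":
            span = (arc.gantry_stop - arc.gantry_start) % 360.0
            gantry = (arc.gantry_start + np.linspace(0.0, span, n_cp)) % 360.0
        beam.ControlPointSequence = []
        for i in range(n_cp):
            cp = Dataset()
            cp.ControlPointIndex = i
            cp.GantryAngle = _fmt(gantry[i])
            cp.GantryRotationDirection = arc.rotation_direction
            cp.CumulativeMetersetWeight = _fmt(arc.meterset[i])
            if i == 0:
                cp.NominalBeamEnergy = "6"
                cp.BeamLimitingDeviceAngle = _fmt(arc.collimator)
                cp.PatientSupportAngle = "0"
                cp.IsocenterPosition = [_fmt(v) for v in plan.isocenter]
            bld = Dataset()
            bld.RTBeamLimitingDeviceType = "MLCX"
            bld.LeafJawPositions = [f"{v:.2f}" for v in arc.mlc[i]]
            cp.BeamLimitingDevicePositionSequence = [bld]
            beam.ControlPointSequence.append(cp)
        ds.BeamSequence.append(beam)

        fg_ref = Dataset()
        fg_ref.ReferencedBeamNumber = b
        fg_ref.BeamMeterset = "400.0"
        fg_refs.append(fg_ref)

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 28
    fg.NumberOfBeams = len(plan.arcs)
    fg.NumberOfBrachyApplicationSetups = 0
    fg.ReferencedBeamSequence = fg_refs
    ds.FractionGroupSequence = [fg]

    path = Path(path)
    ds.save_as(str(path), enforce_file_format=True)
    return path
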