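"""DICOM-RT read/write round-trips and plan retargeting."""

import numpy as np
import pydicom
import pytest

import planmatch as pm
from planmatch import dicom_io
from planmatch.errors import FormatError


def _case_files(case_dir):
    return {p.name[:2]: p for p in case_dir.iterdir()}


# ---------------------------------------------------------------------------
# structure set
# ---------------------------------------------------------------------------


def test_structure_set_round_trip(tmp_path):
    """Contours survive write -> read within 0.01 mm, names verbatim."""
    rng = np.random.default_rng(7)
    sets = []
    for name in ("Prostate", "Bladder_full", "FemHead_L"):
        slices = []
        for z in (0.0, 2.5, 5.0):
            n = int(rng.integers(3, 20))
            xy = rng.uniform(-80, 80, size=(n, 2))
            slices.append(np.column_stack([xy, np.full(n, z)]))
        sets.append(pm.ContourSet(name, slices))
    path = dicom_io.write_structure_set(tmp_path / "rs.dcm", "pat1", sets)
    back = pm.read_structure_set(path)
    assert [c.structure_name for c in back] == [c.structure_name for c in sets]
    for orig, rt in zip(sets, back):
        assert len(rt.slices) == len(orig.slices)
        for a, b in zip(orig.slices, rt.slices):
            np.testing.assert_allclose(b, a, atol=0.01)


def test_structure_set_skips_empty_roi(tmp_path, caplog):
    sets = [pm.ContourSet(n, [np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], float)])
            for n in ("A", "B", "C")]
    path = dicom_io.write_structure_set(tmp_path / "rs.dcm", "pat1", sets)
    ds = pydicom.dcmread(path)
    del ds.ROIContourSequence[1].ContourSequence
    ds.save_as(path, enforce_file_format=True)
    back = pm.read_structure_set(path)
    assert [c.structure_name for c in back] == ["A", "C"]


def test_structure_set_rejects_wrong_modality(base_case):
    with pytest.raises(FormatError):
        pm.read_structure_set(_case_files(base_case)["RD"])


# ---------------------------------------------------------------------------
# dose
# ---------------------------------------------------------------------------


def _random_grid(rng, shape=(6, 5, 4)):
    vals = rng.uniform(0, 75, size=shape)
    vals = np.round(vals / dicom_io.DOSE_SCALING) * dicom_io.DOSE_SCALING
    return pm.DoseGrid(origin=(-10.0, -5.0, 0.0), spacing=(2.0, 2.5, 3.0),
                       values=vals, prescription_dose=70.0)


def test_dose_round_trip(tmp_path):
    grid = _random_grid(np.random.default_rng(1))
    path = dicom_io.write_dose(tmp_path / "rd.dcm", "pat1", grid)
    back = pm.read_dose(path, prescription_dose=70.0)
    np.testing.assert_allclose(back.values, grid.values, atol=1e-6)
    np.testing.assert_allclose(back.origin, grid.origin, atol=1e-5)
    np.testing.assert_allclose(back.spacing, grid.spacing, atol=1e-5)


def test_dose_scaling_is_applied(tmp_path):
    """Stored integers v with scale factor s must read as s*v."""
    grid = _random_grid(np.random.default_rng(2))
    path = dicom_io.write_dose(tmp_path / "rd.dcm", "pat1", grid)
    ds = pydicom.dcmread(path)
    stored = ds.pixel_array.astype(float)
    ds.DoseGridScaling = 2.0 * float(ds.DoseGridScaling)
    path2 = tmp_path / "rd2.dcm"
    ds.save_as(path2, enforce_file_format=True)
    back = pm.read_dose(path2)
    np.testing.assert_allclose(back.values.transpose(2, 1, 0),
                               stored * float(ds.DoseGridScaling), rtol=1e-12)


def test_dose_rejects_2d_and_missing_scaling(tmp_path):
    grid = _random_grid(np.random.default_rng(3))
    path = dicom_io.write_dose(tmp_path / "rd.dcm", "pat1", grid)
    ds = pydicom.dcmread(path)
    del ds.GridFrameOffsetVector
    ds.NumberOfFrames = 1
    ds.save_as(tmp_path / "rd2d.dcm", enforce_file_format=True)
    with pytest.raises(FormatError):
        pm.read_dose(tmp_path / "rd2d.dcm")
    ds = pydicom.dcmread(path)
    del ds.DoseGridScaling
    ds.save_as(tmp_path / "rdns.dcm", enforce_file_format=True)
    with pytest.raises(FormatError):
        pm.read_dose(tmp_path / "rdns.dcm")


# ---------------------------------------------------------------------------
# plan
# ---------------------------------------------------------------------------


def test_plan_round_trip(base_case):
    plan = pm.read_plan(_case_files(base_case)["RP"])
    assert plan.n_arcs == 2
    assert plan.metadata["n_arcs"] == 2
    assert plan.prescription_dose == 70.0
    for arc in plan.arcs:
        assert arc.mlc.shape == (90, 120)
        assert np.all(np.diff(arc.meterset) >= 0)
        assert arc.meterset[0] == 0.0 and arc.meterset[-1] == 1.0


def test_plan_rejects_missing_beams(tmp_path, base_case):
    ds = pydicom.dcmread(_case_files(base_case)["RP"])
    del ds.BeamSequence
    ds.save_as(tmp_path / "rp.dcm", enforce_file_format=True)
    with pytest.raises(FormatError):
        pm.read_plan(tmp_path / "rp.dcm")


# ---------------------------------------------------------------------------
# retargeting
# ---------------------------------------------------------------------------

NEW_PATIENT = {"id": "NEW001", "name": "New^Patient",
               "frame_of_reference": "1.2.3.4.5"}


def test_retarget_identity_changes_only_patient_tags(base_case, tmp_path):
    src = _case_files(base_case)["RP"]
    plan = pm.read_plan(src)
    out = pm.retarget_plan(src, tmp_path / "rp.dcm", NEW_PATIENT, plan.isocenter)
    back = pm.read_plan(out)
    assert back.case_id == "NEW001"
    np.testing.assert_array_equal(back.isocenter, plan.isocenter)
    ds = pydicom.dcmread(out)
    assert ds.FrameOfReferenceUID == "1.2.3.4.5"
    src_ds = pydicom.dcmread(src)
    assert ds.SOPInstanceUID != src_ds.SOPInstanceUID


def test_retarget_shifts_isocenter_exactly(base_case, tmp_path):
    src = _case_files(base_case)["RP"]
    plan = pm.read_plan(src)
    shift = np.array([10.0, -5.0, 3.0])
    out = pm.retarget_plan(src, tmp_path / "rp.dcm", NEW_PATIENT,
                           plan.isocenter + shift)
    back = pm.read_plan(out)
    np.testing.assert_allclose(back.isocenter - plan.isocenter, shift, atol=1e-9)


def test_retarget_preserves_mlc_bytes(base_case, tmp_path):
    """Every leaf position (raw DICOM string) must be byte-identical."""
    src = _case_files(base_case)["RP"]
    out = pm.retarget_plan(src, tmp_path / "rp.dcm", NEW_PATIENT, (1.0, 2.0, 3.0))
    a, b = pydicom.dcmread(src), pydicom.dcmread(out)
    for beam_a, beam_b in zip(a.BeamSequence, b.BeamSequence):
        assert len(beam_a.ControlPointSequence) == len(beam_b.ControlPointSequence)
        for cp_a, cp_b in zip(beam_a.ControlPointSequence, beam_b.ControlPointSequence):
            for bld_a, bld_b in zip(cp_a.BeamLimitingDevicePositionSequence,
                                    cp_b.BeamLimitingDevicePositionSequence):
                assert bld_a["LeafJawPositions"].value == bld_b["LeafJawPositions"].value


def test_retarget_round_trip_arcs_equal(base_case, tmp_path):
    src = _case_files(base_case)["RP"]
    plan = pm.read_plan(src)
    out = pm.retarget_plan(src, tmp_path / "rp.dcm", NEW_PATIENT, (0.0, 0.0, 0.0))
    back = pm.read_plan(out)
    assert back.n_arcs == plan.n_arcs
    for arc_a, arc_b in zip(plan.arcs, back.arcs):
        np.testing.assert_array_equal(arc_a.mlc, arc_b.mlc)
        np.testing.assert_array_equal(arc_a.meterset, arc_b.meterset)
        assert arc_a.rotation_direction == arc_b.rotation_direction
        assert (arc_a.gantry_start, arc_a.gantry_stop) == \
            (arc_b.gantry_start, arc_b.gantry_stop)
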