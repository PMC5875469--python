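"""Name standardization, case ingestion, filtering and persistence."""

import json
import shutil

import numpy as np
import pytest

import planmatch as pm
from planmatch import database
from planmatch.errors import CaseRejectedError, IntegrityError

from conftest import random_cloud


@pytest.mark.parametrize("raw,canonical", [
    ("Bladder_full", "bladder"),
    ("BLADDER", "bladder"),
    ("PTV 78", "target"),
    ("ptv_70Gy", "target"),
    ("Prostate", "target"),
    ("Rectum", "rectum"),
    ("rect_wall", "rectum"),
    ("FemHead_L", "other"),
    ("Body", "other"),
])
def test_standardize_structure_names(raw, canonical):
    assert pm.standardize_structure_names(raw) == canonical


def test_custom_synonym_table(tmp_path):
    table = tmp_path / "syn.tsv"
    table.write_text("blase\tbladder\nzielvolumen\ttarget\n")
    assert pm.standardize_structure_names("Blase 2", table) == "bladder"
    assert pm.standardize_structure_names("Bladder", table) == "other"


# ---------------------------------------------------------------------------
# build_entry
# ---------------------------------------------------------------------------


def test_build_entry_from_synthetic_case(base_entry):
    assert not base_entry.target_cloud.is_empty
    assert set(base_entry.cropped_oar_clouds) == {"bladder", "rectum"}
    assert set(base_entry.dvh_curves) == {"target", "bladder", "rectum"}
    assert base_entry.index_meta["n_arcs"] == base_entry.plan.n_arcs
    assert base_entry.index_meta["prescription_dose"] == 70.0


def test_build_entry_rejects_ambiguous_plans(base_case, tmp_path):
    dup = tmp_path / "dup"
    shutil.copytree(base_case, dup)
    shutil.copy(dup / "RP_caseA.dcm", dup / "RP_copy.dcm")
    with pytest.raises(CaseRejectedError, match="ambiguous"):
        pm.build_entry(dup)


def test_build_entry_rejects_missing_dose(base_case, tmp_path):
    broken = tmp_path / "broken"
    shutil.copytree(base_case, broken)
    (broken / "RD_caseA.dcm").unlink()
    with pytest.raises(CaseRejectedError, match="dose"):
        pm.build_entry(broken)


def test_build_entry_deterministic(base_case):
    a = pm.build_entry(base_case)
    b = pm.build_entry(base_case)
    np.testing.assert_array_equal(a.target_cloud.points, b.target_cloud.points)
    for name in a.cropped_oar_clouds:
        np.testing.assert_array_equal(a.cropped_oar_clouds[name].points,
                                      b.cropped_oar_clouds[name].points)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def _meta_entry(i, **meta):
    defaults = {"physician": "A", "institution": "Main", "machine": "TB1",
                "boost_flag": False, "n_arcs": 2, "prescription_dose": 70.0}
    defaults.update(meta)
    target = random_cloud(np.random.default_rng(i), 10, name="target")
    arcs = [pm.ArcBeam(178.0, 182.0, "CC", 30.0, np.zeros((1, 4)), np.zeros(1))
            for _ in range(defaults["n_arcs"])]
    plan = pm.PlanRecord(f"c{i}", np.zeros(3), arcs, 70.0, defaults)
    return pm.DatabaseEntry(f"c{i}", target, {}, {}, plan, dict(defaults))


@pytest.fixture()
def meta_entries():
    entries = []
    for i in range(10):
        entries.append(_meta_entry(
            i,
            physician="A" if i < 4 else "B",
            boost_flag=i in (0, 5, 9),
            n_arcs=2 if i % 2 == 0 else 1,
            prescription_dose=70.0 + 4.0 * (i % 3),
        ))
    return entries


def test_empty_criteria_match_all(meta_entries):
    assert pm.filter_entries(meta_entries, None) == meta_entries
    assert pm.filter_entries(meta_entries, pm.SearchCriteria()) == meta_entries


def test_boost_filter_counts(meta_entries):
    out = pm.filter_entries(meta_entries, pm.SearchCriteria(boost_flag=False))
    assert len(out) == 7  # 3 of 10 are boost cases by construction


def test_conjunction_equals_intersection(meta_entries):
    both = pm.filter_entries(meta_entries,
                             pm.SearchCriteria(physician="A", n_arcs_min=2,
                                               n_arcs_max=2))
    only_a = pm.filter_entries(meta_entries, pm.SearchCriteria(physician="A"))
    only_2 = pm.filter_entries(meta_entries,
                               pm.SearchCriteria(n_arcs_min=2, n_arcs_max=2))
    assert both == [e for e in only_a if e in only_2]


def test_rx_range_filter(meta_entries):
    out = pm.filter_entries(meta_entries, pm.SearchCriteria(rx_min=72.0))
    assert all(e.index_meta["prescription_dose"] >= 72.0 for e in out)
    assert out  # the constructed set has cases above 72 Gy


def test_filter_idempotent_and_order_preserving(meta_entries):
    crit = pm.SearchCriteria(physician="B")
    once = pm.filter_entries(meta_entries, crit)
    assert pm.filter_entries(once, crit) == once
    ids = [e.case_id for e in once]
    assert ids == sorted(ids, key=lambda c: [e.case_id for e in meta_entries].index(c))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def test_save_load_round_trip(small_db, tmp_path):
    _, entries = small_db
    path = pm.save_database(entries, tmp_path / "db.json")
    back = pm.load_database(path)
    assert [e.case_id for e in back] == [e.case_id for e in entries]
    for a, b in zip(entries, back):
        np.testing.assert_allclose(b.target_cloud.points, a.target_cloud.points,
                                   atol=1e-9)
        assert set(b.cropped_oar_clouds) == set(a.cropped_oar_clouds)
        for name in a.cropped_oar_clouds:
            np.testing.assert_allclose(b.cropped_oar_clouds[name].points,
                                       a.cropped_oar_clouds[name].points, atol=1e-9)
        for name in a.dvh_curves:
            np.testing.assert_allclose(b.dvh_curves[name].volume_percent,
                                       a.dvh_curves[name].volume_percent, atol=1e-9)
        assert b.index_meta == a.index_meta
        for arc_a, arc_b in zip(a.plan.arcs, b.plan.arcs):
            np.testing.assert_array_equal(arc_b.mlc, arc_a.mlc)


def test_empty_database_round_trips(tmp_path):
    path = pm.save_database([], tmp_path / "empty.json")
    assert pm.load_database(path) == []


def test_corrupted_archive_raises(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text("{not json")
    with pytest.raises(IntegrityError):
        pm.load_database(path)


def test_schema_version_mismatch_names_both_versions(small_db, tmp_path):
    _, entries = small_db
    path = pm.save_database(entries[:1], tmp_path / "db.json")
    doc = json.loads(path.read_text())
    doc["schema_version"] = 99
    path.write_text(json.dumps(doc))
    with pytest.raises(IntegrityError, match="99"):
        pm.load_database(path)


def test_index_summary_one_row_per_case(small_db):
    _, entries = small_db
    lines = database.index_summary(entries).strip().splitlines()
    assert len(lines) == len(entries) + 1
    assert lines[0].startswith("case_id")
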