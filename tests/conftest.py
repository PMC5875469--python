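"""Shared fixtures: synthetic cases generated once per session."""

from pathlib import Path

import numpy as np
import pytest

import planmatch as pm
from planmatch import synthetic
from planmatch.synthetic import PhantomSpec


@pytest.fixture(scope="session")
def base_case(tmp_path_factory) -> Path:
    """One deterministic synthetic case directory (RTSTRUCT+RTDOSE+RTPLAN)."""
    out = tmp_path_factory.mktemp("base_case")
    return synthetic.generate_case(PhantomSpec(seed=3), out, "caseA")


@pytest.fixture(scope="session")
def base_entry(base_case) -> pm.DatabaseEntry:
    return pm.build_entry(base_case)


@pytest.fixture(scope="session")
def small_db(tmp_path_factory):
    """Six jittered cases -> (case dirs, database entries)."""
    out = tmp_path_factory.mktemp("small_db")
    dirs, _ = synthetic.generate_database(6, PhantomSpec(), seed=11, out_dir=out)
    entries = [pm.build_entry(d) for d in dirs]
    return dirs, entries


@pytest.fixture(scope="session")
def patient_case(tmp_path_factory) -> Path:
    """A query patient distinct from the small_db cases."""
    out = tmp_path_factory.mktemp("patient")
    spec = synthetic._vary_spec(PhantomSpec(), np.random.default_rng(99),
                                case_seed=42)
    return synthetic.generate_case(spec, out, "patient")


def random_cloud(rng: np.random.Generator, n: int, scale: float = 50.0,
                 name: str = "cloud") -> pm.SurfaceCloud:
    return pm.SurfaceCloud(name, rng.uniform(-scale, scale, size=(n, 3)))
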