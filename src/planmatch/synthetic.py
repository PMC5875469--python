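"""Seeded synthetic pelvic cases written as standard DICOM-RT files.

Every case emulates the male pelvic geometry the retrieval engine is
built for: a prostate-like target (ellipsoid with a smooth, band-limited
seeded radial perturbation), a bladder (sphere, superior-anterior of the
target) and a rectum (posterior cylinder), plus an analytic dose
distribution that equals the prescription inside a 5 mm-expanded target
and falls off as a Gaussian with distance, and a 2-arc VMAT plan with
rectangular MLC apertures fitted to the target extent. Dose is analytic
by design: the engine only needs a plausible high-dose region for
isodose cropping and DVHs, not a physically simulated fluence.

All geometry is fully deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from scipy.special import sph_harm_y

from . import dicom_io
from .dicom_io import ArcBeam, ContourSet, DoseGrid, PlanRecord

log = logging.getLogger(__name__)

N_LEAF_PAIRS = 60
LEAF_WIDTH = 5.0  # mm
LEAF_BOUNDARIES = LEAF_WIDTH * (np.arange(N_LEAF_PAIRS + 1) - N_LEAF_PAIRS / 2)
N_CONTROL_POINTS = 90
TARGET_EXPANSION = 5.0  # mm margin of full prescription around the target


@dataclass
class PhantomSpec:
    """Parameters of one synthetic pelvic case (lengths in mm, dose in Gy)."""

    seed: int = 0
    target_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    target_radii: tuple[float, float, float] = (25.0, 22.0, 20.0)
    deformation_amplitude: float = 3.0
    bladder_offset: tuple[float, float, float] = (0.0, -20.0, 45.0)
    bladder_radius: float = 25.0
    rectum_offset: tuple[float, float, float] = (0.0, 32.0, 0.0)
    rectum_radius: float = 10.0
    rectum_length: float = 90.0
    grid_spacing: float = 2.5
    slice_thickness: float = 2.5
    n_azimuth: int = 72
    prescription_dose: float = 70.0
    dose_falloff_sigma: float = 8.0
    metadata: dict = field(default_factory=lambda: {
        "physician": "A", "institution": "Main", "boost_flag": False,
        "n_arcs": 2, "machine": "TB1",
    })

    def __post_init__(self) -> None:
        for name in ("target_radii", "bladder_radius", "rectum_radius",
                     "rectum_length", "grid_spacing", "slice_thickness",
                     "prescription_dose", "dose_falloff_sigma"):
            v = getattr(self, name)
            if np.any(np.asarray(v) <= 0):
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# target surface: perturbed ellipsoid
# ---------------------------------------------------------------------------


class _TargetSurface:
    """Radial surface r(theta, phi) = ellipsoid radius + seeded perturbation.

    The perturbation is a random real-spherical-harmonic field of degree
    <= 4 (band-limited, hence smooth and self-intersection free at the
    default amplitude), rescaled so its maximum magnitude equals the
    requested deformation amplitude in mm.
    """

    L_MAX = 4

    def __init__(self, radii, amplitude: float, seed: int):
        self.radii = np.asarray(radii, dtype=float)
        self.amplitude = float(amplitude)
        n_basis = sum(2 * l + 1 for l in range(1, self.L_MAX + 1))
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5AFE]))
        self.coeffs = rng.normal(size=n_basis)
        if self.amplitude > 0:
            th = np.linspace(1e-4, np.pi - 1e-4, 181)
            ph = np.linspace(0, 2 * np.pi, 181, endpoint=False)
            tt, pp = np.meshgrid(th, ph, indexing="ij")
            raw = self._raw_perturbation(tt.ravel(), pp.ravel())
            self.scale = self.amplitude / float(np.abs(raw).max())
        else:
            self.scale = 0.0

    def _raw_perturbation(self, theta, phi) -> np.ndarray:
        out = np.zeros(np.shape(theta), dtype=float)
        i = 0
        for l in range(1, self.L_MAX + 1):
            for m in range(-l, l + 1):
                y = sph_harm_y(l, abs(m), theta, phi)
                if m > 0:
                    b = np.sqrt(2.0) * y.real
                elif m < 0:
                    b = np.sqrt(2.0) * y.imag
                else:
                    b = y.real
                out += self.coeffs[i] * b
                i += 1
        return out

    def radius(self, theta, phi) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        ux = np.sin(theta) * np.cos(phi)
        uy = np.sin(theta) * np.sin(phi)
        uz = np.cos(theta)
        r_ell = 1.0 / np.sqrt((ux / self.radii[0]) ** 2
                              + (uy / self.radii[1]) ** 2
                              + (uz / self.radii[2]) ** 2)
        if self.scale == 0.0:
            return r_ell
        return r_ell + self.scale * self._raw_perturbation(theta, phi)


def _slice_polygon(surf: _TargetSurface, center, z: float, n_az: int) -> np.ndarray:
    """Intersection polygon of the radial surface with the plane at z.

    For each azimuth the polar angle solving r(theta, phi) cos(theta) =
    z - cz is found by bisection (the profile is monotone for these
    near-convex shapes).
    """
    dz = z - center[2]
    phis = np.linspace(0.0, 2 * np.pi, n_az, endpoint=False)
    lo = np.full(n_az, 1e-9)
    hi = np.full(n_az, np.pi - 1e-9)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        above = surf.radius(mid, phis) * np.cos(mid) > dz
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    theta = 0.5 * (lo + hi)
    r = surf.radius(theta, phis)
    x = center[0] + r * np.sin(theta) * np.cos(phis)
    y = center[1] + r * np.sin(theta) * np.sin(phis)
    return np.column_stack([x, y, np.full(n_az, z)])


def _slice_range(z_lo: float, z_hi: float, thickness: float) -> np.ndarray:
    k_lo = int(np.ceil(z_lo / thickness))
    k_hi = int(np.floor(z_hi / thickness))
    return thickness * np.arange(k_lo, k_hi + 1)


def _target_contours(spec: PhantomSpec, surf: _TargetSurface) -> ContourSet:
    c = np.asarray(spec.target_center)
    pole = float(np.min(surf.radius(np.full(spec.n_azimuth, 1e-9),
                                    np.linspace(0, 2 * np.pi, spec.n_azimuth,
                                                endpoint=False))))
    bottom = float(np.min(surf.radius(np.full(spec.n_azimuth, np.pi - 1e-9),
                                      np.linspace(0, 2 * np.pi, spec.n_azimuth,
                                                  endpoint=False))))
    zs = _slice_range(c[2] - 0.97 * bottom, c[2] + 0.97 * pole, spec.slice_thickness)
    slices = [_slice_polygon(surf, c, float(z), spec.n_azimuth) for z in zs]
    return ContourSet("Prostate", slices)


def _sphere_contours(name: str, center, radius: float, spec: PhantomSpec) -> ContourSet:
    c = np.asarray(center, dtype=float)
    zs = _slice_range(c[2] - 0.97 * radius, c[2] + 0.97 * radius,
                      spec.slice_thickness)
    phis = np.linspace(0.0, 2 * np.pi, spec.n_azimuth, endpoint=False)
    slices = []
    for z in zs:
        rho = float(np.sqrt(max(radius ** 2 - (z - c[2]) ** 2, 0.0)))
        if rho < 1.0:
            continue
        slices.append(np.column_stack([c[0] + rho * np.cos(phis),
                                       c[1] + rho * np.sin(phis),
                                       np.full(spec.n_azimuth, z)]))
    return ContourSet(name, slices)


def _cylinder_contours(name: str, center, radius: float, length: float,
                       spec: PhantomSpec) -> ContourSet:
    c = np.asarray(center, dtype=float)
    zs = _slice_range(c[2] - length / 2, c[2] + length / 2, spec.slice_thickness)
    phis = np.linspace(0.0, 2 * np.pi, spec.n_azimuth, endpoint=False)
    slices = [
        np.column_stack([c[0] + radius * np.cos(phis),
                         c[1] + radius * np.sin(phis),
                         np.full(spec.n_azimuth, z)])
        for z in zs
    ]
    return ContourSet(name, slices)


# ---------------------------------------------------------------------------
# dose and plan
# ---------------------------------------------------------------------------


def _make_dose_grid(spec: PhantomSpec, surf: _TargetSurface,
                    contour_sets: list[ContourSet]) -> DoseGrid:
    """Analytic dose on a grid covering all structures plus a 10 mm margin."""
    pts = np.concatenate([cs.all_points() for cs in contour_sets], axis=0)
    lo = np.floor((pts.min(axis=0) - 10.0) / spec.grid_spacing) * spec.grid_spacing
    hi = pts.max(axis=0) + 10.0
    shape = np.ceil((hi - lo) / spec.grid_spacing).astype(int) + 1
    axes = [lo[a] + spec.grid_spacing * np.arange(shape[a]) for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    v = np.stack([gx - spec.target_center[0],
                  gy - spec.target_center[1],
                  gz - spec.target_center[2]], axis=-1)
    rho = np.linalg.norm(v, axis=-1)
    rho_safe = np.maximum(rho, 1e-9)
    theta = np.arccos(np.clip(v[..., 2] / rho_safe, -1.0, 1.0))
    phi = np.arctan2(v[..., 1], v[..., 0])
    r_surf = surf.radius(theta.ravel(), phi.ravel()).reshape(rho.shape)
    outside = np.maximum(rho - (r_surf + TARGET_EXPANSION), 0.0)
    dose = spec.prescription_dose * np.exp(
        -outside ** 2 / (2.0 * spec.dose_falloff_sigma ** 2)
    )
    # store at the writer's fixed quantization so in-memory == on-disk
    dose = np.round(dose / dicom_io.DOSE_SCALING) * dicom_io.DOSE_SCALING
    return DoseGrid(lo, np.full(3, spec.grid_spacing), dose,
                    prescription_dose=spec.prescription_dose)


def _make_plan(spec: PhantomSpec, case_id: str, target_pts: np.ndarray) -> PlanRecord:
    """A VMAT plan: isocenter at the target COM, rectangular MLC apertures
    fitted to the target's extent, 90 control points per arc."""
    iso = target_pts.mean(axis=0)
    x_lo = float(target_pts[:, 0].min() - iso[0]) - 2.0
    x_hi = float(target_pts[:, 0].max() - iso[0]) + 2.0
    z_lo = float(target_pts[:, 2].min() - iso[2]) - 2.0
    z_hi = float(target_pts[:, 2].max() - iso[2]) + 2.0
    leaf_centers = 0.5 * (LEAF_BOUNDARIES[:-1] + LEAF_BOUNDARIES[1:])
    open_pair = (leaf_centers >= z_lo) & (leaf_centers <= z_hi)
    bank_a = np.where(open_pair, x_lo, 0.0)
    bank_b = np.where(open_pair, x_hi, 0.0)
    row = np.round(np.concatenate([bank_a, bank_b]), 2)
    mlc = np.tile(row, (N_CONTROL_POINTS, 1))
    meterset = np.round(np.linspace(0.0, 1.0, N_CONTROL_POINTS), 6)
    arcs = [ArcBeam(178.0, 182.0, "CC", 30.0, mlc, meterset)]
    n_arcs = int(spec.metadata.get("n_arcs", 2))
    if n_arcs >= 2:
        arcs.append(ArcBeam(182.0, 178.0, "CW", 330.0, mlc.copy(), meterset.copy()))
    meta = dict(spec.metadata)
    meta["n_arcs"] = len(arcs)
    return PlanRecord(case_id, np.round(iso, 6), arcs,
                      spec.prescription_dose, meta)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def generate_case(spec: PhantomSpec, out_dir: str | Path,
                  case_id: str = "case_000") -> Path:
    """Write one synthetic case (RTSTRUCT + RTDOSE + RTPLAN) to out_dir/case_id."""
    case_dir = Path(out_dir) / case_id
    case_dir.mkdir(parents=True, exist_ok=True)
    surf = _TargetSurface(spec.target_radii, spec.deformation_amplitude, spec.seed)
    target = _target_contours(spec, surf)
    bladder_center = np.asarray(spec.target_center) + np.asarray(spec.bladder_offset)
    rectum_center = np.asarray(spec.target_center) + np.asarray(spec.rectum_offset)
    bladder = _sphere_contours("Bladder", bladder_center, spec.bladder_radius, spec)
    rectum = _cylinder_contours("Rectum", rectum_center, spec.rectum_radius,
                                spec.rectum_length, spec)
    structures = [target, bladder, rectum]
    grid = _make_dose_grid(spec, surf, structures)
    plan = _make_plan(spec, case_id, target.all_points())

    meta = dict(spec.metadata)
    meta.setdefault("patient_name", case_id)
    dicom_io.write_structure_set(case_dir / f"RS_{case_id}.dcm", case_id,
                                 structures, meta=meta)
    dicom_io.write_dose(case_dir / f"RD_{case_id}.dcm", case_id, grid, meta=meta)
    dicom_io.write_plan(case_dir / f"RP_{case_id}.dcm", plan, LEAF_BOUNDARIES)
    return case_dir


def _vary_spec(base: PhantomSpec, rng: np.random.Generator,
               case_seed: int) -> PhantomSpec:
    """Per-case jitter: radii +-15 %, offsets +-10 mm, sampled metadata."""
    radii = tuple(r * rng.uniform(0.85, 1.15) for r in base.target_radii)
    center = tuple(c + rng.uniform(-10, 10) for c in base.target_center)
    bladder_offset = tuple(o + rng.uniform(-10, 10) for o in base.bladder_offset)
    rectum_offset = (base.rectum_offset[0] + rng.uniform(-5, 5),
                     base.rectum_offset[1] + rng.uniform(-5, 5),
                     base.rectum_offset[2] + rng.uniform(-10, 10))
    metadata = {
        "physician": str(rng.choice(["A", "B", "C"])),
        "institution": str(rng.choice(["Main", "North"])),
        "boost_flag": bool(rng.random() < 0.3),
        "n_arcs": int(rng.choice([1, 2], p=[0.3, 0.7])),
        "machine": str(rng.choice(["TB1", "TB2"])),
    }
    return replace(
        base, seed=case_seed, target_center=center, target_radii=radii,
        bladder_offset=bladder_offset,
        bladder_radius=base.bladder_radius * rng.uniform(0.85, 1.15),
        rectum_offset=rectum_offset,
        rectum_radius=base.rectum_radius * rng.uniform(0.9, 1.1),
        prescription_dose=float(rng.choice([70.0, 74.0, 78.0])),
        metadata=metadata,
    )


def generate_database(n: int, base_spec: PhantomSpec, seed: int,
                      out_dir: str | Path) -> tuple[list[Path], Path]:
    """Write n seeded case directories plus a ground-truth manifest (TSV)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(int(seed))
    dirs, rows = [], []
    for i in range(n):
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = _vary_spec(base_spec, rng, case_seed)
        case_id = f"case_{seed}_{i:03d}"
        dirs.append(generate_case(spec, out_dir, case_id))
        rows.append({
            "case_id": case_id, "seed": spec.seed,
            "rx_gy": spec.prescription_dose,
            "radius_x": spec.target_radii[0], "radius_y": spec.target_radii[1],
            "radius_z": spec.target_radii[2],
            "center_x": spec.target_center[0], "center_y": spec.target_center[1],
            "center_z": spec.target_center[2],
            **spec.metadata,
        })
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False, float_format="%.6f")
    return dirs, manifest


def _smooth_displacement(points: np.ndarray, amplitude: float,
                         seed: int) -> np.ndarray:
    """Smooth seeded in-plane (x, y) displacement field, max norm = amplitude.

    A superposition of three long-wavelength sinusoids per component;
    the z component is zero so contour slices stay planar.
    """
    if amplitude <= 0:
        return np.zeros_like(points)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xDEF0]))
    disp = np.zeros_like(points)
    for comp in range(2):  # x and y only
        acc = np.zeros(points.shape[0])
        for _ in range(3):
            k = rng.normal(size=3)
            k = k / np.linalg.norm(k) * (2 * np.pi / rng.uniform(35.0, 70.0))
            acc += rng.normal() * np.sin(points @ k + rng.uniform(0, 2 * np.pi))
        disp[:, comp] = acc
    norms = np.linalg.norm(disp, axis=1)
    disp *= amplitude / max(float(norms.max()), 1e-12)
    return disp


def plant_near_duplicate(patient_case: str | Path, translation, deformation: float,
                         seed: int, out_dir: str | Path,
                         case_id: str = "planted") -> Path:
    """Copy a case's geometry, translated and smoothly deformed, as a new case.

    Creates the ground truth for retrieval tests: a database case whose
    anatomy matches the patient up to a known rigid shift and a smooth
    deformation of the stated amplitude (mm).
    """
    from .database import discover_case_files  # local import to avoid cycle

    translation = np.asarray(translation, dtype=float)
    files = discover_case_files(patient_case)
    case_dir = Path(out_dir) / case_id
    case_dir.mkdir(parents=True, exist_ok=True)

    contour_sets = dicom_io.read_structure_set(files["structures"])
    all_pts = np.concatenate([cs.all_points() for cs in contour_sets], axis=0)
    disp_all = _smooth_displacement(all_pts, deformation, seed)
    new_sets, ofs = [], 0
    for cs in contour_sets:
        new_slices = []
        for poly in cs.slices:
            n = poly.shape[0]
            new_slices.append(poly + disp_all[ofs:ofs + n] + translation)
            ofs += n
        new_sets.append(ContourSet(cs.structure_name, new_slices))
    dicom_io.write_structure_set(case_dir / f"RS_{case_id}.dcm", case_id, new_sets,
                                 meta={"patient_name": case_id})

    plan = dicom_io.read_plan(files["plan"])
    grid = dicom_io.read_dose(files["dose"], prescription_dose=plan.prescription_dose)
    shifted = DoseGrid(grid.origin + translation, grid.spacing, grid.values,
                       prescription_dose=grid.prescription_dose)
    dicom_io.write_dose(case_dir / f"RD_{case_id}.dcm", case_id, shifted,
                        meta={"patient_name": case_id})

    frame_uid = dicom_io.generate_uid(dicom_io._UID_PREFIX,
                                      entropy_srcs=[case_id, "frame"])
    dicom_io.retarget_plan(files["plan"], case_dir / f"RP_{case_id}.dcm",
                           {"id": case_id, "name": case_id,
                            "frame_of_reference": frame_uid},
                           plan.isocenter + translation)
    return case_dir
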