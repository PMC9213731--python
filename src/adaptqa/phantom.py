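"""Synthetic cohort generator for adaptive-SBRT plan evaluation studies.

Emulates, per "patient", a pancreatic-SBRT planning scene — a spherical GTV
expanded to CTV (+5 mm) and PTV (+2 mm), with three parametric
gastro-intestinal organs (ellipsoidal stomach, curved duodenal tube abutting
or slightly overlapping the PTV, and a multi-loop bowel tube) — and, per
"fraction":

* a *manual* (ground-truth) structure set: planning organs warped by a
  smooth random interfraction displacement field, targets held fixed
  (emulating fiducial-based target alignment);
* one or more *auto-contour* sets: the manual organs warped by a smaller
  smooth error field, optionally with a signed bias pushing organ surfaces
  along the PTV distance gradient near the target (negative bias pulls the
  contour away from the PTV — near-target underestimation; positive bias
  pushes it toward/into the PTV — overestimation);
* four dose grids: the planning dose carried unchanged onto the fraction
  (non-adapted, NoAd), and a surrogate replan for the manual set and for
  each auto set.

The dose model is an analytic SBRT-like falloff (full dose deep inside the
PTV, prescription at the PTV surface at the stated isodose percentage,
exponential falloff outside), and the "optimizer" is a constraint-capping
surrogate: it clamps dose to ``cap_Gy`` on the organs it is given.  With
``cap_Gy`` below the 35 Gy near-maximum threshold, replanning on the *true*
contours satisfies V35 < 0.5 cc by construction; replanning on erroneous
auto contours leaves the mis-contoured near-target organ volume uncapped,
which is the causal mechanism the cohort analysis is designed to detect.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy import ndimage

from . import io as qio
from .grids import (
    BinaryStructure,
    DoseGrid,
    GridGeometry,
    StructureSet,
    distance_map,
    union,
)

__all__ = [
    "AutoContourProfile",
    "DoseParams",
    "PhantomConfig",
    "FractionBundle",
    "demo_config",
    "smooth_displacement_field",
    "deform_structures",
    "falloff_dose",
    "surrogate_replan",
    "build_planning_anatomy",
    "simulate_patient",
    "simulate_cohort",
    "generate_cohort",
    "load_cohort",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AutoContourProfile:
    """Error model of one auto-contouring method.

    ``global_amplitude_mm`` scales a smooth random error field (95th
    percentile of voxel displacement magnitude).  ``near_ptv_bias_mm`` is a
    signed surface shift applied within ``bias_radius_mm`` of the PTV
    (cosine-tapered to zero over ``bias_taper_mm``); negative values pull
    the contour away from the PTV (underestimation near the target).
    ``bias_probability`` is the per-fraction chance the bias is applied,
    letting a cohort mix biased and unbiased fractions.
    """

    name: str
    global_amplitude_mm: float = 2.0
    corr_length_mm: float = 30.0
    near_ptv_bias_mm: float = 0.0
    bias_radius_mm: float = 3.0
    bias_taper_mm: float = 4.0
    bias_organs: tuple[str, ...] | None = None  # None = all OARs
    bias_probability: float = 1.0

    def __post_init__(self) -> None:
        if self.near_ptv_bias_mm != 0.0 and self.bias_radius_mm <= 0:
            raise ValueError("bias_radius_mm must be > 0 when a near-PTV bias is set")
        if not 0.0 <= self.bias_probability <= 1.0:
            raise ValueError("bias_probability must lie in [0, 1]")


@dataclass(frozen=True)
class DoseParams:
    """Prescription and analytic dose-model parameters.

    40 Gy in 5 fractions prescribed to the 80% isodose line gives a maximum
    dose of 40 / 0.80 = 50 Gy.  ``falloff_lambda_mm`` sets the exponential
    dose gradient outside the PTV; ``cap_Gy`` is the surrogate optimizer's
    clamp on organ voxels and must stay below the 35 Gy near-maximum
    constraint so that replanning on true contours is compliant by
    construction.
    """

    rx_Gy: float = 40.0
    iso_pct: float = 80.0
    falloff_lambda_mm: float = 25.0
    cap_Gy: float = 34.0
    cap_margin_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.rx_Gy <= 0 or not 0 < self.iso_pct <= 100:
            raise ValueError("rx_Gy must be > 0 and iso_pct in (0, 100]")
        if self.falloff_lambda_mm <= 0:
            raise ValueError("falloff_lambda_mm must be > 0")
        if not 0 < self.cap_Gy < 35.0:
            raise ValueError("cap_Gy must be in (0, 35) Gy")

    @property
    def dmax_Gy(self) -> float:
        return self.rx_Gy / (self.iso_pct / 100.0)


def _default_profiles() -> tuple[AutoContourProfile, ...]:
    # two DIR-like error profiles: one slightly underestimating near the
    # target, one overestimating (pushing into the PTV)
    return (
        AutoContourProfile("dirA", global_amplitude_mm=2.0, near_ptv_bias_mm=-2.0),
        AutoContourProfile("dirB", global_amplitude_mm=3.0, near_ptv_bias_mm=+3.0),
    )


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of a synthetic cohort."""

    shape: tuple[int, int, int] = (56, 56, 48)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    gtv_radius_mm: float = 10.0
    ctv_margin_mm: float = 5.0
    ptv_margin_mm: float = 2.0
    interfraction_amplitude_mm: float = 10.0
    interfraction_corr_mm: float = 25.0
    patient_jitter_mm: float = 3.0
    profiles: tuple[AutoContourProfile, ...] = field(default_factory=_default_profiles)
    dose: DoseParams = field(default_factory=DoseParams)
    n_patients: int = 3
    fractions_per_patient: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.fractions_per_patient < 1:
            raise ValueError("need at least one patient and one fraction")
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValueError("auto-contour profile names must be unique")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.shape, self.spacing_mm)

    def to_dict(self) -> dict:
        return asdict(self)


def demo_config(seed: int = 0, n_patients: int = 3, fractions: int = 3) -> PhantomConfig:
    """Small default cohort configuration used in examples and smoke tests."""
    return PhantomConfig(n_patients=n_patients, fractions_per_patient=fractions, seed=seed)


@dataclass
class FractionBundle:
    """Everything belonging to one treatment fraction."""

    patient: str
    fraction: str
    man_set: StructureSet
    auto_sets: dict[str, StructureSet]
    doses: dict[str, DoseGrid]
    bias_applied: dict[str, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# displacement fields and warping
# ---------------------------------------------------------------------------


def smooth_displacement_field(
    geometry: GridGeometry,
    amplitude_mm: float,
    corr_length_mm: float,
    seed,
) -> np.ndarray:
    """Zero-mean smooth random vector field, shape ``(3, *grid)``, in mm.

    Gaussian white noise per component is low-pass filtered to the given
    correlation length and rescaled so the 95th percentile of the voxel
    displacement magnitude equals ``amplitude_mm`` exactly.  Deterministic
    given the seed.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude must be >= 0")
    if corr_length_mm <= 0:
        raise ValueError("correlation length must be > 0")
    if amplitude_mm == 0:
        return np.zeros((3, *geometry.shape))
    rng = np.random.default_rng(seed)
    sigma_vox = [corr_length_mm / s for s in geometry.spacing_mm]
    comps = []
    for _ in range(3):
        noise = rng.standard_normal(geometry.shape)
        # periodic filtering keeps the field statistically stationary; edge
        # padding modes inflate variance at the volume boundary and would make
        # the global p95 unrepresentative of motion near the (central) target
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
        comps.append(smooth - smooth.mean())
    fld = np.stack(comps)
    mag = np.sqrt((fld**2).sum(axis=0))
    p95 = float(np.percentile(mag, 95))
    if p95 == 0.0:
        return np.zeros_like(fld)
    return fld * (amplitude_mm / p95)


def _ptv_bias_field(
    ptv: BinaryStructure,
    bias_mm: float,
    bias_radius_mm: float,
    bias_taper_mm: float,
    ptv_signed: np.ndarray | None = None,
) -> np.ndarray:
    """Sampling displacement implementing the near-PTV surface bias.

    The returned field ``s`` is used as ``mask_new(x) = mask_old(x + s(x))``
    (nearest-neighbor pull-back), with ``s = bias * w(d) * g_hat`` where
    ``g_hat`` is the unit gradient of the PTV distance (pointing away from
    the PTV) and ``w`` is 1 within ``bias_radius_mm`` of the PTV, tapering
    cosine-smoothly to 0 over ``bias_taper_mm``.  Negative bias therefore
    retracts organ surfaces away from the PTV.
    """
    if bias_radius_mm <= 0:
        raise ValueError("bias_radius_mm must be > 0 when a near-PTV bias is set")
    if ptv_signed is None:
        ptv_signed = distance_map(ptv, signed=True)
    spacing = ptv.geometry.spacing_mm
    grads = np.gradient(ptv_signed, *spacing)
    g = np.stack(grads)
    norm = np.sqrt((g**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        g_hat = np.where(norm > 1e-9, g / norm, 0.0)
    d_out = np.maximum(ptv_signed, 0.0)  # bias acts from the PTV surface outward
    taper = max(bias_taper_mm, 1e-9)
    w = np.where(
        d_out <= bias_radius_mm,
        1.0,
        np.where(
            d_out <= bias_radius_mm + taper,
            0.5 * (1.0 + np.cos(np.pi * (d_out - bias_radius_mm) / taper)),
            0.0,
        ),
    )
    return bias_mm * w * g_hat


def deform_structures(
    sset: StructureSet,
    fld: np.ndarray,
    ptv: BinaryStructure | None = None,
    near_ptv_bias_mm: float = 0.0,
    bias_radius_mm: float = 3.0,
    bias_taper_mm: float = 4.0,
    bias_organs: tuple[str, ...] | None = None,
    ptv_signed: np.ndarray | None = None,
) -> StructureSet:
    """Warp OAR masks by a displacement field; targets stay fixed.

    Each OAR mask is resampled by nearest neighbor at the displaced voxel
    coordinates, so masks remain binary and on-grid.  The optional near-PTV
    bias adds the signed surface shift of :func:`_ptv_bias_field` to the
    organs in ``bias_organs`` (default: all OARs).  GTV and PTV are never
    deformed, emulating fiducial-based target alignment.
    """
    geom = sset.geometry
    if fld.shape != (3, *geom.shape):
        raise ValueError(f"field shape {fld.shape} does not match grid {geom.shape}")
    if near_ptv_bias_mm != 0.0:
        if ptv is None:
            ptv = sset.single("PTV")
        bias_fld = _ptv_bias_field(
            ptv, near_ptv_bias_mm, bias_radius_mm, bias_taper_mm, ptv_signed=ptv_signed
        )
    else:
        bias_fld = None

    idx = np.indices(geom.shape, dtype=float)
    spacing = np.asarray(geom.spacing_mm).reshape(3, 1, 1, 1)
    base_coords = idx + fld / spacing

    out = StructureSet(geometry=geom, rx_Gy=sset.rx_Gy)
    for name, struct in sset.structures.items():
        role = sset.roles[name]
        if role in ("GTV", "PTV") or role == "other":
            out.add(BinaryStructure(name, geom, struct.mask.copy()), role)
            continue
        coords = base_coords
        if bias_fld is not None and (bias_organs is None or name in bias_organs):
            coords = idx + (fld + bias_fld) / spacing
        # linear pull-back + 0.5 threshold: keeps masks binary/on-grid while
        # still responding to sub-voxel displacements (a pure nearest-neighbor
        # resample silently discards any shift below half a voxel)
        warped = (
            ndimage.map_coordinates(
                struct.mask.astype(np.float32), coords, order=1, mode="constant", cval=0.0
            )
            >= 0.5
        )
        out.add(BinaryStructure(name, geom, warped), role)
    return out


# ---------------------------------------------------------------------------
# dose surrogates
# ---------------------------------------------------------------------------


def falloff_dose(
    ptv: BinaryStructure,
    dose: DoseParams,
    ptv_signed: np.ndarray | None = None,
) -> DoseGrid:
    """Analytic SBRT-like dose: Dmax inside, rx at the PTV surface, exponential
    falloff outside.

    With signed PTV distance ``sd``: dose = Dmax for sd <= -3 mm, a linear
    ramp from Dmax down to ``iso_pct``% of Dmax (= rx) at sd = 0, and
    ``rx * exp(-sd / lambda)`` outside; strictly decreasing with sd outside.
    """
    if ptv.is_empty:
        raise ValueError("cannot build a dose around an empty PTV")
    if ptv_signed is None:
        ptv_signed = distance_map(ptv, signed=True)
    iso = dose.iso_pct / 100.0
    dmax = dose.dmax_Gy
    sd = ptv_signed
    ramp = 1.0 + (1.0 - iso) * sd / 3.0  # sd in [-3, 0]: 1 -> iso
    g = np.where(
        sd <= -3.0,
        1.0,
        np.where(sd <= 0.0, ramp, iso * np.exp(-sd / dose.falloff_lambda_mm)),
    )
    return DoseGrid(ptv.geometry, dmax * g, dose.rx_Gy)


def surrogate_replan(
    base: DoseGrid,
    oar_set: StructureSet | list[BinaryStructure],
    cap_Gy: float,
    cap_margin_mm: float = 0.0,
) -> DoseGrid:
    """Constraint-capping stand-in for a full inverse replan.

    Clamps the base dose to ``cap_Gy`` on every voxel within
    ``cap_margin_mm`` of any organ in ``oar_set`` (organ voxels inside the
    PTV included — target coverage loss emerges exactly where organs overlap
    the target); dose is never increased anywhere.  Idempotent.
    """
    if cap_Gy <= 0:
        raise ValueError("cap_Gy must be > 0")
    organs = oar_set.by_role("OAR") if isinstance(oar_set, StructureSet) else list(oar_set)
    organs = [o for o in organs if not o.is_empty]
    if not organs:
        return DoseGrid(base.geometry, base.dose_Gy.copy(), base.rx_Gy)
    region = union(organs, name="_cap_region")
    mask = region.mask
    if cap_margin_mm > 0:
        dist = ndimage.distance_transform_edt(~mask, sampling=base.geometry.spacing_mm)
        mask = dist <= cap_margin_mm + 1e-9
    capped = np.where(mask, np.minimum(base.dose_Gy, cap_Gy), base.dose_Gy)
    return DoseGrid(base.geometry, capped, base.rx_Gy)


# ---------------------------------------------------------------------------
# anatomy construction
# ---------------------------------------------------------------------------


def _ellipsoid_mask(geom: GridGeometry, center_mm, semi_mm) -> np.ndarray:
    xs, ys, zs = geom.coordinate_grids()
    cx, cy, cz = center_mm
    ax, ay, az = semi_mm
    return ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2 <= 1.0


def _sphere(geom: GridGeometry, center_mm, r_mm, name: str) -> BinaryStructure:
    return BinaryStructure(name, geom, _ellipsoid_mask(geom, center_mm, (r_mm,) * 3))


def _tube_mask(geom: GridGeometry, path_mm: np.ndarray, radius_mm: float) -> np.ndarray:
    """Voxelize a tube of given radius around a polyline of world points."""
    spacing = np.asarray(geom.spacing_mm)
    idx = np.rint((path_mm - np.asarray(geom.origin_mm)) / spacing).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(geom.shape)), axis=1)
    idx = idx[ok]
    centerline = np.zeros(geom.shape, dtype=bool)
    centerline[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if not centerline.any():
        return centerline
    dist = ndimage.distance_transform_edt(~centerline, sampling=geom.spacing_mm)
    return dist <= radius_mm + 1e-9


def build_planning_anatomy(config: PhantomConfig, rng: np.random.Generator) -> StructureSet:
    """Planning structure set: targets centered on the grid, OARs around them.

    Organ placement gets per-patient jitter so the cohort spans a range of
    target-organ proximities: the duodenum abuts / slightly overlaps the
    PTV, the stomach sits a few mm away, the bowel loops are furthest.
    """
    geom = config.geometry
    center = np.array([(n - 1) * s / 2.0 for n, s in zip(geom.shape, geom.spacing_mm)])
    jit = lambda scale=1.0: rng.uniform(-config.patient_jitter_mm, config.patient_jitter_mm) * scale

    gtv = _sphere(geom, center, config.gtv_radius_mm, "GTV")
    ptv_r = config.gtv_radius_mm + config.ctv_margin_mm + config.ptv_margin_mm
    ptv = _sphere(geom, center, ptv_r, "PTV")

    # duodenum: tube arcing around the target, grazing/overlapping the PTV at
    # mid-arc and sweeping outward toward both ends (so the organ has volume
    # both near the target and tens of mm away, as a real duodenum does)
    duo_tube_r = 7.0
    duo_arc_r = ptv_r + duo_tube_r - 1.5 + jit(0.5)  # ~1-2 mm overlap with PTV
    theta = np.linspace(-1.5, 1.5, 201)
    duo_r = duo_arc_r + 14.0 * (np.abs(theta) / 1.5) ** 2
    duo_path = center + np.stack(
        [
            duo_r * np.cos(theta),
            duo_r * np.sin(theta),
            6.0 * np.sin(0.8 * theta) + jit(0.5),
        ],
        axis=1,
    )
    duodenum = BinaryStructure("duodenum", geom, _tube_mask(geom, duo_path, duo_tube_r))

    # stomach: ellipsoid on the opposite side, small gap to the PTV
    sto_semi = np.array([22.0, 15.0, 17.0]) + rng.uniform(-2, 2, size=3)
    sto_center = center + np.array(
        [-(ptv_r + sto_semi[0] + 2.0 + jit(0.5)), 8.0 + jit(), 4.0 + jit()]
    )
    stomach = BinaryStructure("stomach", geom, _ellipsoid_mask(geom, sto_center, sto_semi))

    # bowel: sinuous tube passing below the target
    bow_tube_r = 8.0
    t = np.linspace(0.0, 1.0, 241)
    bow_path = center + np.stack(
        [
            (t - 0.5) * 90.0,
            22.0 * np.sin(4.0 * np.pi * t) + jit(),
            -(ptv_r + bow_tube_r + 6.0 + jit(0.5)) + 5.0 * np.sin(2.0 * np.pi * t),
        ],
        axis=1,
    )
    bowel = BinaryStructure("bowel", geom, _tube_mask(geom, bow_path, bow_tube_r))

    sset = StructureSet(geometry=geom, rx_Gy=config.dose.rx_Gy)
    sset.add(gtv, "GTV")
    sset.add(ptv, "PTV")
    sset.add(stomach, "OAR")
    sset.add(duodenum, "OAR")
    sset.add(bowel, "OAR")
    return sset


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _copy_set(sset: StructureSet) -> StructureSet:
    out = StructureSet(geometry=sset.geometry, rx_Gy=sset.rx_Gy)
    for name, s in sset.structures.items():
        out.add(BinaryStructure(name, sset.geometry, s.mask.copy()), sset.roles[name])
    return out


def simulate_patient(
    config: PhantomConfig, patient_index: int
) -> tuple[StructureSet, DoseGrid, list[FractionBundle]]:
    """Planning set, planning dose and all fraction bundles for one patient."""
    rng = np.random.default_rng([config.seed, patient_index])
    planning = build_planning_anatomy(config, rng)
    ptv = planning.single("PTV")
    ptv_signed = distance_map(ptv, signed=True)
    base = falloff_dose(ptv, config.dose, ptv_signed=ptv_signed)
    planned = surrogate_replan(base, planning, config.dose.cap_Gy, config.dose.cap_margin_mm)

    bundles = []
    for f in range(config.fractions_per_patient):
        ifx_fld = smooth_displacement_field(
            config.geometry,
            config.interfraction_amplitude_mm,
            config.interfraction_corr_mm,
            seed=[config.seed, patient_index, f, 1],
        )
        man = deform_structures(planning, ifx_fld)
        auto_sets: dict[str, StructureSet] = {}
        bias_applied: dict[str, bool] = {}
        doses: dict[str, DoseGrid] = {
            "planned": planned,
            "noad": DoseGrid(base.geometry, planned.dose_Gy.copy(), planned.rx_Gy),
            "replan_man": surrogate_replan(
                base, man, config.dose.cap_Gy, config.dose.cap_margin_mm
            ),
        }
        for k, prof in enumerate(config.profiles):
            err_fld = smooth_displacement_field(
                config.geometry,
                prof.global_amplitude_mm,
                prof.corr_length_mm,
                seed=[config.seed, patient_index, f, 2, k],
            )
            bias_rng = np.random.default_rng([config.seed, patient_index, f, 3, k])
            apply_bias = (
                prof.near_ptv_bias_mm != 0.0 and bias_rng.random() < prof.bias_probability
            )
            auto = deform_structures(
                man,
                err_fld,
                ptv=ptv,
                near_ptv_bias_mm=prof.near_ptv_bias_mm if apply_bias else 0.0,
                bias_radius_mm=prof.bias_radius_mm,
                bias_taper_mm=prof.bias_taper_mm,
                bias_organs=prof.bias_organs,
                ptv_signed=ptv_signed,
            )
            auto_sets[prof.name] = auto
            bias_applied[prof.name] = bool(apply_bias)
            doses[f"replan_{prof.name}"] = surrogate_replan(
                base, auto, config.dose.cap_Gy, config.dose.cap_margin_mm
            )
        bundles.append(
            FractionBundle(
                patient=f"p{patient_index:02d}",
                fraction=f"f{f:02d}",
                man_set=man,
                auto_sets=auto_sets,
                doses=doses,
                bias_applied=bias_applied,
            )
        )
    return planning, planned, bundles


def simulate_cohort(config: PhantomConfig) -> Iterator[FractionBundle]:
    """In-memory generator over every fraction bundle of the cohort."""
    for p in range(config.n_patients):
        _, _, bundles = simulate_patient(config, p)
        yield from bundles


def _array_sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def generate_cohort(config: PhantomConfig, out_dir: str | Path) -> dict:
    """Write the cohort to ``out_dir`` and return (and save) its manifest.

    Layout: ``p00/f00/{man,auto_<name>}/`` structure-set directories plus
    ``dose_<plan>.nii.gz`` volumes per fraction.  The manifest records the
    config, every file with its role, per-fraction bias flags, and content
    hashes of the voxel arrays; rerunning with the same config and seed
    reproduces it byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patients = []
    for p in range(config.n_patients):
        _, _, bundles = simulate_patient(config, p)
        fractions = []
        for bundle in bundles:
            fdir = out_dir / bundle.patient / bundle.fraction
            sets_entry = {}
            qio.write_structure_set(bundle.man_set, fdir / "man")
            sets_entry["man"] = {
                "path": f"{bundle.patient}/{bundle.fraction}/man",
                "hashes": {n: _array_sha(s.mask) for n, s in bundle.man_set.structures.items()},
            }
            for name, aset in bundle.auto_sets.items():
                qio.write_structure_set(aset, fdir / f"auto_{name}")
                sets_entry[f"auto_{name}"] = {
                    "path": f"{bundle.patient}/{bundle.fraction}/auto_{name}",
                    "bias_applied": bundle.bias_applied[name],
                    "hashes": {n: _array_sha(s.mask) for n, s in aset.structures.items()},
                }
            doses_entry = {}
            for plan, dose in bundle.doses.items():
                fname = f"dose_{plan}.nii.gz"
                qio.write_dose(dose, fdir / fname)
                doses_entry[plan] = {
                    "path": f"{bundle.patient}/{bundle.fraction}/{fname}",
                    "hash": _array_sha(dose.dose_Gy),
                }
            fractions.append(
                {"fraction": bundle.fraction, "structure_sets": sets_entry, "doses": doses_entry}
            )
        patients.append({"patient": f"p{p:02d}", "fractions": fractions})
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "patients": patients,
        "auto_methods": [prof.name for prof in config.profiles],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def load_cohort(cohort_dir: str | Path) -> Iterator[FractionBundle]:
    """Iterate fraction bundles from a :func:`generate_cohort` output tree."""
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"not a cohort directory (missing {manifest_path})")
    manifest = json.loads(manifest_path.read_text())
    for patient in manifest["patients"]:
        for frac in patient["fractions"]:
            sets = frac["structure_sets"]
            man = qio.read_structure_set(cohort_dir / sets["man"]["path"])
            auto_sets = {}
            bias_applied = {}
            for key, entry in sets.items():
                if not key.startswith("auto_"):
                    continue
                name = key[len("auto_"):]
                auto_sets[name] = qio.read_structure_set(cohort_dir / entry["path"])
                bias_applied[name] = bool(entry.get("bias_applied", False))
            doses = {
                plan: qio.read_dose(cohort_dir / entry["path"])
                for plan, entry in frac["doses"].items()
            }
            yield FractionBundle(
                patient=patient["patient"],
                fraction=frac["fraction"],
                man_set=man,
                auto_sets=auto_sets,
                doses=doses,
                bias_applied=bias_applied,
            )


def config_from_dict(data: dict) -> PhantomConfig:
    """Rebuild a :class:`PhantomConfig` from its ``to_dict`` form (or YAML)."""
    data = dict(data)
    if "profiles" in data:
        data["profiles"] = tuple(
            AutoContourProfile(**{**p, "bias_organs": tuple(p["bias_organs"]) if p.get("bias_organs") else None})
            if isinstance(p, dict)
            else p
            for p in data["profiles"]
        )
    if isinstance(data.get("dose"), dict):
        data["dose"] = DoseParams(**data["dose"])
    for key in ("shape", "spacing_mm"):
        if key in data:
            data[key] = tuple(data[key])
    return PhantomConfig(**data)
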