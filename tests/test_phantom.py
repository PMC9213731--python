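"""Synthetic-cohort generator: displacement fields, warping, dose surrogates
and cohort layout/determinism."""

import numpy as np
import pytest

from adaptqa.grids import BinaryStructure, GridGeometry, StructureSet, distance_map
from adaptqa.metrics import clip_to_target
from adaptqa.phantom import (
    AutoContourProfile,
    DoseParams,
    PhantomConfig,
    build_planning_anatomy,
    deform_structures,
    falloff_dose,
    generate_cohort,
    load_cohort,
    simulate_patient,
    smooth_displacement_field,
    surrogate_replan,
)


SMALL = PhantomConfig(
    shape=(40, 40, 36),
    n_patients=2,
    fractions_per_patient=2,
    profiles=(AutoContourProfile("auto", global_amplitude_mm=2.0, near_ptv_bias_mm=-4.0),),
    seed=11,
)


class TestDisplacementField:
    def test_zero_amplitude_zero_field(self):
        f = smooth_displacement_field(SMALL.geometry, 0.0, 20.0, seed=1)
        assert not f.any()

    def test_deterministic_given_seed(self):
        f1 = smooth_displacement_field(SMALL.geometry, 5.0, 20.0, seed=42)
        f2 = smooth_displacement_field(SMALL.geometry, 5.0, 20.0, seed=42)
        assert np.array_equal(f1, f2)
        f3 = smooth_displacement_field(SMALL.geometry, 5.0, 20.0, seed=43)
        assert not np.array_equal(f1, f3)

    def test_p95_magnitude_equals_amplitude(self):
        f = smooth_displacement_field(SMALL.geometry, 5.0, 30.0, seed=7)
        mag = np.sqrt((f**2).sum(axis=0))
        assert np.percentile(mag, 95) == pytest.approx(5.0, abs=1e-6)


class TestDeform:
    def test_zero_field_zero_bias_identity(self):
        rng = np.random.default_rng(0)
        planning = build_planning_anatomy(SMALL, rng)
        zero = np.zeros((3, *SMALL.geometry.shape))
        out = deform_structures(planning, zero)
        for name in planning.names:
            assert np.array_equal(out[name].mask, planning[name].mask)

    def test_targets_never_deformed(self):
        rng = np.random.default_rng(0)
        planning = build_planning_anatomy(SMALL, rng)
        f = smooth_displacement_field(SMALL.geometry, 8.0, 20.0, seed=5)
        out = deform_structures(planning, f)
        for role in ("GTV", "PTV"):
            assert np.array_equal(out.single(role).mask, planning.single(role).mask)

    def test_masks_stay_binary_on_grid(self):
        rng = np.random.default_rng(0)
        planning = build_planning_anatomy(SMALL, rng)
        f = smooth_displacement_field(SMALL.geometry, 8.0, 20.0, seed=5)
        out = deform_structures(planning, f)
        for name in out.oar_names:
            assert out[name].mask.dtype == np.bool_
            assert out[name].mask.shape == tuple(SMALL.geometry.shape)

    def test_negative_bias_shrinks_near_target_volume(self):
        rng = np.random.default_rng(0)
        planning = build_planning_anatomy(SMALL, rng)
        ptv = planning.single("PTV")
        zero = np.zeros((3, *SMALL.geometry.shape))
        biased = deform_structures(
            planning, zero, ptv=ptv, near_ptv_bias_mm=-6.0, bias_organs=("duodenum",)
        )
        before = clip_to_target(planning["duodenum"], ptv, 5.0).volume_cc
        after = clip_to_target(biased["duodenum"], ptv, 5.0).volume_cc
        assert after < before

    def test_positive_bias_grows_near_target_volume(self):
        rng = np.random.default_rng(0)
        planning = build_planning_anatomy(SMALL, rng)
        ptv = planning.single("PTV")
        zero = np.zeros((3, *SMALL.geometry.shape))
        biased = deform_structures(
            planning, zero, ptv=ptv, near_ptv_bias_mm=+4.0, bias_organs=("duodenum",)
        )
        before = clip_to_target(planning["duodenum"], ptv, 5.0).volume_cc
        after = clip_to_target(biased["duodenum"], ptv, 5.0).volume_cc
        assert after > before

    def test_bias_without_radius_rejected(self):
        with pytest.raises(ValueError, match="bias_radius"):
            AutoContourProfile("x", near_ptv_bias_mm=-2.0, bias_radius_mm=0.0)


class TestFalloffDose:
    def setup_method(self):
        geom = GridGeometry((60, 60, 60), (1.0, 1.0, 1.0))
        mask = np.zeros(geom.shape, dtype=bool)
        xs = np.arange(60) - 29.5
        r2 = xs[:, None, None] ** 2 + xs[None, :, None] ** 2 + xs[None, None, :] ** 2
        mask[r2 <= 15.0**2] = True
        self.ptv = BinaryStructure("PTV", geom, mask)
        self.params = DoseParams()

    def test_deep_interior_gets_dmax(self):
        dose = falloff_dose(self.ptv, self.params)
        # 40 Gy prescribed to the 80% isodose: maximum dose is 50 Gy
        assert dose.dose_Gy[30, 30, 30] == pytest.approx(50.0)

    def test_prescription_bracketed_at_surface(self):
        # voxel centers straddle the PTV surface; the innermost outside shell
        # and outermost inside shell must bracket the 40 Gy prescription
        dose = falloff_dose(self.ptv, self.params)
        sd = distance_map(self.ptv, signed=True)
        inside_shell = (sd >= -1.01) & (sd < 0)
        outside_shell = (sd > 0) & (sd <= 1.01)
        assert dose.dose_Gy[inside_shell].min() >= 40.0
        assert dose.dose_Gy[outside_shell].max() <= 40.0
        assert dose.dose_Gy[outside_shell].min() >= 40.0 * np.exp(-1.01 / self.params.falloff_lambda_mm)

    def test_monotone_falloff_outside(self):
        dose = falloff_dose(self.ptv, self.params)
        lam = self.params.falloff_lambda_mm
        sd = distance_map(self.ptv, signed=True)
        at_lam = dose.dose_Gy[np.abs(sd - lam) < 0.5].mean()
        at_2lam = dose.dose_Gy[np.abs(sd - 2 * lam) < 0.5].mean() if (sd > 2 * lam - 0.5).any() else 0
        assert at_2lam < at_lam


class TestSurrogateReplan:
    def test_empty_oar_set_is_identity(self):
        rng = np.random.default_rng(0)
        planning = build_planning_anatomy(SMALL, rng)
        base = falloff_dose(planning.single("PTV"), SMALL.dose)
        out = surrogate_replan(base, [], 34.0)
        assert np.array_equal(out.dose_Gy, base.dose_Gy)

    def test_caps_organ_voxels(self):
        rng = np.random.default_rng(0)
        planning = build_planning_anatomy(SMALL, rng)
        base = falloff_dose(planning.single("PTV"), SMALL.dose)
        out = surrogate_replan(base, planning, 34.0)
        for name in planning.oar_names:
            assert out.dose_Gy[planning[name].mask].max() <= 34.0

    def test_never_increases_and_idempotent(self):
        rng = np.random.default_rng(0)
        planning = build_planning_anatomy(SMALL, rng)
        base = falloff_dose(planning.single("PTV"), SMALL.dose)
        once = surrogate_replan(base, planning, 34.0)
        twice = surrogate_replan(once, planning, 34.0)
        assert np.all(once.dose_Gy <= base.dose_Gy)
        assert np.array_equal(once.dose_Gy, twice.dose_Gy)


class TestAnatomy:
    def test_duodenum_abuts_or_overlaps_ptv(self):
        rng = np.random.default_rng(3)
        planning = build_planning_anatomy(PhantomConfig(), rng)
        ptv = planning.single("PTV")
        sd = distance_map(ptv, signed=True)
        assert sd[planning["duodenum"].mask].min() < 2.0

    def test_organs_nonempty_and_disjoint_from_gtv(self):
        rng = np.random.default_rng(4)
        planning = build_planning_anatomy(PhantomConfig(), rng)
        gtv = planning.single("GTV")
        for name in planning.oar_names:
            assert not planning[name].is_empty
            assert not (planning[name].mask & gtv.mask).any()


class TestCohortGeneration:
    def test_fraction_layout_counts(self, tmp_path):
        manifest = generate_cohort(SMALL, tmp_path / "cohort")
        assert len(manifest["patients"]) == 2
        n_fx = sum(len(p["fractions"]) for p in manifest["patients"])
        assert n_fx == 4
        bundles = list(load_cohort(tmp_path / "cohort"))
        assert len(bundles) == 4
        for b in bundles:
            assert set(b.auto_sets) == {"auto"}
            assert set(b.doses) == {"planned", "noad", "replan_man", "replan_auto"}

    def test_rerun_is_reproducible(self, tmp_path):
        m1 = generate_cohort(SMALL, tmp_path / "c1")
        m2 = generate_cohort(SMALL, tmp_path / "c2")
        assert (tmp_path / "c1" / "manifest.json").read_bytes() == (
            tmp_path / "c2" / "manifest.json"
        ).read_bytes()
        b1 = next(load_cohort(tmp_path / "c1"))
        b2 = next(load_cohort(tmp_path / "c2"))
        for name in b1.man_set.names:
            assert np.array_equal(b1.man_set[name].mask, b2.man_set[name].mask)
        for plan in b1.doses:
            assert np.array_equal(b1.doses[plan].dose_Gy, b2.doses[plan].dose_Gy)

    def test_error_free_profile_matches_man_replan(self):
        cfg = PhantomConfig(
            shape=(40, 40, 36),
            n_patients=1,
            fractions_per_patient=1,
            profiles=(AutoContourProfile("perfect", global_amplitude_mm=0.0),),
            seed=2,
        )
        _, _, bundles = simulate_patient(cfg, 0)
        b = bundles[0]
        for name in b.man_set.names:
            assert np.array_equal(b.auto_sets["perfect"][name].mask, b.man_set[name].mask)
        assert np.array_equal(
            b.doses["replan_perfect"].dose_Gy, b.doses["replan_man"].dose_Gy
        )

    def test_noad_equals_planning_dose(self):
        _, planned, bundles = simulate_patient(SMALL, 0)
        for b in bundles:
            assert np.array_equal(b.doses["noad"].dose_Gy, planned.dose_Gy)


class TestConfigValidation:
    def test_cap_at_or_above_constraint_rejected(self):
        with pytest.raises(ValueError, match="cap_Gy"):
            DoseParams(cap_Gy=35.0)

    def test_duplicate_profile_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            PhantomConfig(profiles=(AutoContourProfile("a"), AutoContourProfile("a")))
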