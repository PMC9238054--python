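import numpy as np
import pytest
from dataclasses import replace

from lsfg_superpix.synthetic import (
    BranchingParams,
    CohortGeometry,
    EffectModel,
    SyntheticPatientSpec,
    generate_cohort,
    generate_vessel_tree,
    render_scan,
    to_cohort_patients,
)


def patient(t=10.0, irradiated_eye="OD", seed=99):
    return SyntheticPatientSpec(
        patient_id="P001", time_from_treatment=t, irradiated_eye=irradiated_eye,
        sbp=136.0, dbp=80.0, iop_irradiated=14.4, iop_fellow=15.2,
        dose_to_disc=38.0, distance_tumor_to_disc=5.0, rng_seed=seed,
    )


class TestEffectModel:
    def test_multiplier_shape(self):
        eff = EffectModel()
        assert eff.flow_multiplier(0.0, True) == 1.0
        assert eff.flow_multiplier(60.0, True) == pytest.approx(0.4)
        assert eff.flow_multiplier(144.0, True) == pytest.approx(0.4)  # floor
        assert eff.flow_multiplier(144.0, False) == 1.0  # fellow eye flat

    def test_multiplier_monotone_nonincreasing(self):
        eff = EffectModel()
        ts = np.linspace(0, 150, 40)
        ms = [eff.flow_multiplier(t, True) for t in ts]
        assert all(a >= b for a, b in zip(ms, ms[1:]))
        assert min(ms) >= eff.m_min > 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"baseline_vessel_mbr": -1.0},
            {"scan_noise_sd": -0.5},
            {"m_min": 0.0},
            {"m_min": 1.5},
            {"undefined_pixel_fraction": 1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EffectModel(**kwargs)


class TestVesselTree:
    def test_fraction_bounds_full_frame(self):
        mask = generate_vessel_tree((360, 750), seed=1)
        assert 0.02 <= mask.mean() <= 0.20

    def test_fraction_bounds_small_frame(self, small_geometry):
        mask = generate_vessel_tree((64, 128), seed=3, branching=small_geometry.branching)
        assert 0.02 <= mask.mean() <= 0.20

    def test_seeded_determinism(self):
        a = generate_vessel_tree((64, 128), seed=7)
        b = generate_vessel_tree((64, 128), seed=7)
        assert np.array_equal(a, b)

    def test_zero_branches_leaves_only_trunk(self):
        """With no children the tree reduces to the root trunk walk."""
        trunk_only = BranchingParams(n_trunks=1, n_branches=0, depth=2)
        no_depth = BranchingParams(n_trunks=1, n_branches=2, depth=0)
        a = generate_vessel_tree((64, 128), seed=5, branching=trunk_only)
        b = generate_vessel_tree((64, 128), seed=5, branching=no_depth)
        assert np.array_equal(a, b)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_vessel_tree((16, 128), seed=0)


class TestRenderScan:
    def test_time_zero_equals_fellow_expectation(self, small_geometry):
        """At t = 0 the irradiation multiplier is 1: the scan of the treated
        eye is identical to what the same eye would show untreated."""
        treated = render_scan(patient(t=0.0, irradiated_eye="OD"), "OD", 1,
                              geometry=small_geometry)
        untreated = render_scan(patient(t=0.0, irradiated_eye="OS"), "OD", 1,
                                geometry=small_geometry)
        assert np.array_equal(treated.mbr, untreated.mbr, equal_nan=True)

    def test_multiplier_floor_at_late_times(self, small_geometry):
        """At t = 60 months the defaults give m = 0.4: mean flow of the
        treated eye is ~0.4x its untreated counterpart."""
        eff = EffectModel(scan_noise_sd=0.1, undefined_pixel_fraction=0.0)
        treated = render_scan(patient(t=60.0, irradiated_eye="OD"), "OD", 1,
                              effect=eff, geometry=small_geometry)
        untreated = render_scan(patient(t=60.0, irradiated_eye="OS"), "OD", 1,
                                effect=eff, geometry=small_geometry)
        ratio = treated.mbr.mean() / untreated.mbr.mean()
        assert ratio == pytest.approx(0.4, abs=0.02)

    def test_no_undefined_pixels_when_fraction_zero(self, small_geometry):
        eff = EffectModel(undefined_pixel_fraction=0.0)
        scan = render_scan(patient(), "OD", 1, effect=eff, geometry=small_geometry)
        assert scan.valid.all()

    def test_undefined_fraction_matches_request(self, small_geometry):
        eff = EffectModel(undefined_pixel_fraction=0.05)
        scan = render_scan(patient(), "OD", 1, effect=eff, geometry=small_geometry)
        assert (~scan.valid).mean() == pytest.approx(0.05, abs=0.01)

    def test_all_flow_non_negative(self, small_geometry):
        eff = EffectModel(scan_noise_sd=5.0)  # heavy noise still clips at 0
        scan = render_scan(patient(), "OD", 2, effect=eff, geometry=small_geometry)
        assert (scan.valid_values() >= 0).all()

    def test_bad_scan_index_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            render_scan(patient(), "OD", 4, geometry=small_geometry)

    def test_anatomy_shared_across_repeat_scans(self, small_geometry):
        eff = EffectModel(scan_noise_sd=0.0, undefined_pixel_fraction=0.0)
        s1 = render_scan(patient(), "OD", 1, effect=eff, geometry=small_geometry)
        s2 = render_scan(patient(), "OD", 2, effect=eff, geometry=small_geometry)
        assert np.array_equal(s1.mbr, s2.mbr)


class TestGenerateCohort:
    def test_counts(self, small_geometry):
        entries = generate_cohort(4, seed=2, geometry=small_geometry)
        assert len(entries) == 4
        assert sum(len(scans) for _, scans in entries) == 24
        for spec, scans in entries:
            assert sorted({s.eye for s in scans}) == ["OD", "OS"]
            assert [s.scan_index for s in scans if s.eye == "OD"] == [1, 2, 3]

    def test_covariates_plausible(self, small_geometry):
        entries = generate_cohort(12, seed=8, geometry=small_geometry)
        for spec, _ in entries:
            assert spec.sbp > spec.dbp > 0
            assert 0.5 <= spec.time_from_treatment <= 144.0
            assert spec.iop_irradiated >= 0 and spec.iop_fellow >= 0

    def test_seeded_reproducibility(self, small_geometry):
        a = generate_cohort(3, seed=11, geometry=small_geometry)
        b = generate_cohort(3, seed=11, geometry=small_geometry)
        for (spec_a, scans_a), (spec_b, scans_b) in zip(a, b):
            assert spec_a == spec_b
            for sa, sb in zip(scans_a, scans_b):
                assert np.array_equal(sa.mbr, sb.mbr, equal_nan=True)
                assert np.array_equal(sa.valid, sb.valid)

    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError, match="at least 2"):
            generate_cohort(1)

    def test_irradiated_mean_flow_decreases_with_time(self, small_geometry):
        """Expected treated-eye flow declines in t until the m_min floor."""
        eff = EffectModel(scan_noise_sd=0.1, undefined_pixel_fraction=0.0)
        means = []
        for t in (0.0, 20.0, 40.0, 60.0, 100.0):
            scan = render_scan(patient(t=t), "OD", 1, effect=eff,
                               geometry=small_geometry)
            means.append(scan.mbr.mean())
        assert means[0] > means[1] > means[2] > means[3]
        assert means[3] == pytest.approx(means[4], rel=0.02)  # floor reached

    def test_to_cohort_patients_structure(self, small_geometry):
        entries = generate_cohort(2, seed=4, geometry=small_geometry)
        patients = to_cohort_patients(entries, small_geometry)
        assert len(patients) == 2
        for p, (spec, _) in zip(patients, entries):
            assert p.irradiated_eye == spec.irradiated_eye
            assert len(p.scans["OD"]) == 3 and len(p.scans["OS"]) == 3
            assert p.disc_radius == small_geometry.disc_radius


def test_patient_spec_invariants():
    with pytest.raises(ValueError):
        replace(patient(), sbp=70.0)  # sbp below dbp
    with pytest.raises(ValueError):
        replace(patient(), time_from_treatment=-1.0)
    with pytest.raises(ValueError):
        replace(patient(), iop_fellow=-2.0)
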