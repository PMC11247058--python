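"""Generator contracts: determinism, realized ranges, closed-form round trips."""

import numpy as np
import pandas as pd
import pytest

from clotlab import histo, mech
from clotlab import synthetic as syn
from clotlab.ctimg import measure_scan_pair, place_rois, roi_mean_density
from clotlab.synthetic import (
    CTPhantomParams,
    DEFAULT_TRUTH,
    GenerativeTruth,
    InfeasibleFeaturesError,
    LinearModel,
    cohort_table,
    draw_feasible_features,
    generate_cohort,
    generate_ct_phantom,
    generate_label_mask,
    generate_mech_trace,
)


class TestCohort:
    def test_default_design_yields_87_clots(self, default_cohort):
        assert len(default_cohort) == 87

    def test_same_seed_reproduces_identical_tables(self):
        t1 = cohort_table(generate_cohort(seed=42))
        t2 = cohort_table(generate_cohort(seed=42))
        pd.testing.assert_frame_equal(t1, t2)
        t3 = cohort_table(generate_cohort(seed=43))
        assert not t3.equals(t1)

    def test_realized_contents_span_study_ranges(self, default_cohort_table):
        t = default_cohort_table
        assert t.rbc_content.min() < 1.0 and t.rbc_content.max() > 95.0
        assert t.platelet_content.min() < 1.0 and t.platelet_content.max() > 80.0
        assert t.rbc_content.between(0, 100).all()
        assert t.platelet_content.between(0, 100).all()

    def test_zero_coefficient_truth_collapses_to_intercept(self):
        truth = GenerativeTruth(ncct=LinearModel(b0=40.0)).zero_noise()
        t = cohort_table(generate_cohort(truth, seed=0))
        assert np.allclose(t.ncct_density, 40.0)

    def test_contraction_concentrates_rbcs_with_platelets(self):
        # serum expulsion: realized RBC content rises with platelet conc at fixed volume
        model = DEFAULT_TRUTH.contraction
        for f in (0.005, 0.02, 0.05, 0.40):
            contents = [model.realize(f, p, rng=None)[0] for p in (30, 90, 270)]
            assert contents == sorted(contents)
            assert contents[0] < contents[-1]

    def test_diameter_scales_with_retained_volume(self, default_cohort_table):
        t = default_cohort_table
        small = t[t.rbc_volume_fraction < 0.4]
        ratio = small.diameter / small.retained_volume_fraction ** (1 / 3)
        assert np.allclose(ratio, DEFAULT_TRUTH.syringe_diameter_large)

    def test_blending_volumes_consistent(self, default_cohort_table):
        t = default_cohort_table
        assert np.allclose(t.v_prp + t.v_rbc + t.v_pdp, t.total_volume)
        assert np.allclose(t.v_prp * t.prp_platelet_conc, t.target_platelet_conc * t.total_volume)


class TestMechTraceGeneration:
    def test_spec_targets_round_trip(self):
        targets = {
            "low_stiffness": 2.0,
            "high_stiffness": 200.0,
            "hysteresis_loss": 50.0,
            "plastic_strain": 30.0,
        }
        trace, geom, analytic = generate_mech_trace(targets, diameter_mm=5.0)
        ext = mech.extract_features(trace, geom)
        assert ext.low_strain_stiffness == pytest.approx(2.0, rel=5e-3)
        assert ext.high_strain_stiffness == pytest.approx(200.0, rel=5e-3)
        assert ext.hysteresis_loss == pytest.approx(50.0, rel=5e-3)
        assert ext.plastic_strain == pytest.approx(30.0, rel=5e-3)

    def test_reversible_limit_unloading_coincides_with_loading(self):
        targets = dict(low_stiffness=2.0, high_stiffness=50.0, hysteresis_loss=0.0, plastic_strain=0.0)
        trace, geom, _ = generate_mech_trace(targets, diameter_mm=5.0, n_cycles=1)
        stress = mech.to_nominal_stress(trace, geom)
        cycle = mech.segment_cycles(np.asarray(trace.strain), stress, 1)[0]
        assert mech.hysteresis_loss(cycle) == pytest.approx(0.0, abs=1e-9)

    def test_doubling_stress_scales_stiffness_only(self):
        base = dict(low_stiffness=1.5, high_stiffness=80.0, hysteresis_loss=45.0, plastic_strain=25.0)
        doubled = dict(base, low_stiffness=3.0, high_stiffness=160.0)
        tr1, g1, _ = generate_mech_trace(base, diameter_mm=5.0)
        tr2, g2, _ = generate_mech_trace(doubled, diameter_mm=5.0)
        f1 = mech.extract_features(tr1, g1)
        f2 = mech.extract_features(tr2, g2)
        assert f2.low_strain_stiffness == pytest.approx(2 * f1.low_strain_stiffness, rel=1e-6)
        assert f2.high_strain_stiffness == pytest.approx(2 * f1.high_strain_stiffness, rel=1e-6)
        assert f2.hysteresis_loss == pytest.approx(f1.hysteresis_loss, rel=1e-6)
        assert f2.plastic_strain == pytest.approx(f1.plastic_strain, rel=1e-6)

    def test_infeasible_feature_set_raises(self):
        bad = dict(low_stiffness=-1.0, high_stiffness=10.0, hysteresis_loss=50.0, plastic_strain=30.0)
        with pytest.raises(InfeasibleFeaturesError):
            generate_mech_trace(bad, diameter_mm=5.0)

    def test_refining_sampling_reduces_errors(self):
        targets = dict(low_stiffness=1.0, high_stiffness=60.0, hysteresis_loss=60.0, plastic_strain=40.0)
        errs = []
        for d_eps in (0.4, 0.2, 0.1, 0.05):
            trace, geom, _ = generate_mech_trace(targets, diameter_mm=5.0, d_eps_pct=d_eps, n_cycles=1)
            ext = mech.extract_features(trace, geom, expected_cycles=1)
            errs.append(
                abs(ext.hysteresis_loss - targets["hysteresis_loss"])
                + abs(ext.plastic_strain - targets["plastic_strain"])
            )
        assert errs[-1] <= errs[0]
        assert errs[-1] < 0.05

    def test_softening_decays_peak_stress(self):
        targets = dict(low_stiffness=2.0, high_stiffness=100.0, hysteresis_loss=50.0, plastic_strain=30.0)
        trace, geom, analytic = generate_mech_trace(targets, diameter_mm=5.0, softening=0.9)
        peaks = analytic.peak_stress_per_cycle
        assert len(peaks) == 10
        assert np.allclose(np.diff(np.log(peaks)), np.log(0.9))
        ext = mech.extract_features(trace, geom)
        assert ext.peak_stress_per_cycle == pytest.approx(peaks, rel=1e-9)

    def test_projection_returns_feasible_set(self, rng):
        raw = {
            "low_stiffness": -0.2,
            "high_stiffness": 3.0,
            "hysteresis_loss": 102.0,
            "plastic_strain": 81.0,
        }
        projected, adjusted = syn.project_feasible_features(raw)
        assert adjusted
        generate_mech_trace(projected, diameter_mm=5.0)  # must not raise


class TestPhantoms:
    def phantom_pair(self, truth=None, sigma=0.0, seed=0):
        truth = truth or DEFAULT_TRUTH.zero_noise()
        clot = generate_cohort(truth, seed=seed)[40]
        params = CTPhantomParams(noise_sigma=sigma)
        return clot, generate_ct_phantom(clot, params, seed=seed)

    def test_noise_free_ncct_density_exact(self):
        clot, (ncct_img, cect_img) = self.phantom_pair()
        res = measure_scan_pair(ncct_img, cect_img, sample_diameter=clot.diameter)
        assert res.ncct_density == pytest.approx(clot.true_values["ncct_density"], abs=1e-12)

    def test_noise_free_cect_increase_exact(self):
        clot, (ncct_img, cect_img) = self.phantom_pair()
        res = measure_scan_pair(ncct_img, cect_img, sample_diameter=clot.diameter)
        expected = max(0.0, clot.true_values["cect_increase"])
        assert res.cect_increase == pytest.approx(expected, abs=1e-12)

    def test_fixed_penetration_increment_round_trip(self):
        # a truth whose CECT model is a pure 12-HU offset
        truth = GenerativeTruth(cect=LinearModel(b0=12.0)).zero_noise()
        clot, (ncct_img, cect_img) = self.phantom_pair(truth=truth)
        res = measure_scan_pair(ncct_img, cect_img, sample_diameter=clot.diameter)
        assert res.cect_increase == pytest.approx(12.0, abs=1e-12)

    def test_same_seed_identical_phantoms(self):
        _, (a1, c1) = self.phantom_pair(sigma=3.0, seed=9)
        _, (a2, c2) = self.phantom_pair(sigma=3.0, seed=9)
        assert np.array_equal(a1.hu, a2.hu)
        assert np.array_equal(c1.hu, c2.hu)

    def test_clot_larger_than_tube_rejected(self):
        clot = generate_cohort(seed=0)[0]
        with pytest.raises(ValueError, match="tube"):
            generate_ct_phantom(clot, CTPhantomParams(tube_diameter=clot.diameter / 2))


class TestLabelMasks:
    def test_exact_style_recovers_contents_exactly(self):
        msb, cd42b = generate_label_mask(76.85, 10.83, style="exact", seed=1)
        assert histo.content_percent(msb, histo.RBC) == pytest.approx(76.85, abs=1e-9)
        assert histo.content_percent(cd42b, histo.PLATELET) == pytest.approx(10.83, abs=1e-9)

    def test_zero_composition_is_fibrin_other_interior(self):
        msb, cd42b = generate_label_mask(0.0, 0.0, wbc_pct=0.0, seed=0)
        interior = msb.labels[msb.labels != histo.BACKGROUND]
        assert np.all(interior == histo.FIBRIN_OTHER)

    def test_blob_style_mean_recovery_error_below_1pct(self):
        errs = []
        for seed in range(20):
            msb, cd42b = generate_label_mask(40.0, 25.0, style="blob", seed=seed)
            errs.append(abs(histo.content_percent(msb, histo.RBC) - 40.0))
            errs.append(abs(histo.content_percent(cd42b, histo.PLATELET) - 25.0))
        assert np.mean(errs) < 1.0

    def test_impossible_composition_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            generate_label_mask(120.0, 10.0)

    def test_same_seed_identical_masks(self):
        m1, c1 = generate_label_mask(30.0, 20.0, seed=7)
        m2, c2 = generate_label_mask(30.0, 20.0, seed=7)
        assert np.array_equal(m1.labels, m2.labels)
        assert np.array_equal(c1.labels, c2.labels)


def test_recovery_study_smoke_unbiased():
    rec = syn.recovery_study(n_replicates=25, seed=3)
    assert len(rec) == 12
    # with 25 replicates the estimates should already sit close to truth
    big = rec[rec.beta_true.abs() > 0.01]
    assert (big.rel_bias.abs() < 0.10).all()
    assert rec.coverage.between(0.7, 1.0).all()
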