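"""Cyclic-compression feature extraction against analytic oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from clotlab import mech
from clotlab.mech import (
    CycleBranch,
    MechTrace,
    SectionGeometry,
    hysteresis_loss,
    plastic_strain,
    secant_modulus,
    segment_cycles,
    to_nominal_stress,
)


def triangular_trace(n_cycles=10, d_eps=0.1, peak=80.0, area=10.0, slope_kpa=2.0):
    """Ideal triangular strain with linear elastic stress (kPa = slope * fraction)."""
    up = np.arange(0.0, peak + d_eps / 2, d_eps)
    down = up[-2::-1]
    strain = np.concatenate([np.concatenate([up if k == 0 else up[1:], down]) for k in range(n_cycles)])
    time = np.arange(strain.size) * d_eps / 10.0
    stress = slope_kpa * strain / 100.0
    return MechTrace(time=time, strain=strain, force=stress * area / 1000.0)


class TestNominalStress:
    def test_unit_conversion(self):
        tr = MechTrace(time=np.arange(3.0), strain=np.zeros(3), force=np.full(3, 0.01))
        geom = SectionGeometry(cross_sectional_area=10.0, feret_diameter=3.6)
        assert to_nominal_stress(tr, geom) == pytest.approx([1.0, 1.0, 1.0])

    def test_zero_force_gives_zero_stress(self):
        tr = MechTrace(time=np.arange(3.0), strain=np.zeros(3), force=np.zeros(3))
        geom = SectionGeometry(cross_sectional_area=5.0, feret_diameter=2.5)
        assert np.all(to_nominal_stress(tr, geom) == 0)

    def test_round_trip_recovers_force(self, rng):
        force = rng.uniform(0, 0.5, 100)
        tr = MechTrace(time=np.arange(100.0), strain=np.zeros(100), force=force)
        geom = SectionGeometry(cross_sectional_area=17.3, feret_diameter=4.7)
        back = to_nominal_stress(tr, geom) * geom.cross_sectional_area / 1000.0
        assert np.allclose(back, force, rtol=1e-12)

    def test_bad_area_rejected(self):
        with pytest.raises(ValueError):
            SectionGeometry(cross_sectional_area=0.0, feret_diameter=1.0)


class TestSegmentCycles:
    def test_ideal_triangle_gives_expected_cycles(self):
        tr = triangular_trace(n_cycles=10)
        stress = to_nominal_stress(tr, SectionGeometry(10.0, 3.6))
        cycles = segment_cycles(tr.strain, stress, 10)
        assert len(cycles) == 10
        for c in cycles:
            assert np.all(np.diff(c.loading[:, 0]) >= 0)
            assert np.all(np.diff(c.unloading[:, 0]) <= 0)
            assert c.peak_strain == pytest.approx(80.0)

    def test_constant_strain_raises_with_count(self):
        strain = np.zeros(100)
        with pytest.raises(ValueError, match="0 cycles detected"):
            segment_cycles(strain, strain, 10)

    def test_noisy_triangle_matches_argmax_oracle(self, rng):
        tr = triangular_trace(n_cycles=10)
        noisy = np.clip(tr.strain + rng.normal(0, 0.2, tr.strain.size), 0.0, 99.0)
        period = 2 * 800  # samples per cycle at 0.1% steps
        cycles = segment_cycles(noisy, np.zeros_like(noisy), 10)
        for k, c in enumerate(cycles):
            # brute-force oracle: argmax within each nominal period
            lo, hi = k * period, min((k + 1) * period + 1, noisy.size)
            oracle_peak = lo + int(np.argmax(noisy[lo:hi]))
            peak_strain_oracle = noisy[oracle_peak]
            assert c.peak_strain == pytest.approx(peak_strain_oracle, abs=1e-9)


def branch_from_fn(fn, lo, hi, n=2001, reverse=False):
    e = np.linspace(lo, hi, n)
    if reverse:
        e = e[::-1]
    return np.column_stack([e, fn(e / 100.0)])


class TestSecantModulus:
    def test_linear_stress_recovers_slope_in_both_windows(self):
        branch = CycleBranch(1, branch_from_fn(lambda x: 2.0 * x, 0, 80), branch_from_fn(lambda x: 2.0 * x, 0, 80, reverse=True))
        assert secant_modulus(branch, (0, 10)) == pytest.approx(2.0)
        assert secant_modulus(branch, (75, 80)) == pytest.approx(2.0)

    def test_zero_stress_gives_zero_modulus(self):
        branch = CycleBranch(1, branch_from_fn(lambda x: 0.0 * x, 0, 80), branch_from_fn(lambda x: 0.0 * x, 0, 80, reverse=True))
        assert secant_modulus(branch, (0, 10)) == 0.0

    @pytest.mark.parametrize("window", [(0.0, 10.0), (75.0, 80.0)])
    def test_polynomial_matches_integral_ols_oracle(self, window):
        A, B = 1.0, 100.0
        fn = lambda x: A * x + B * x**5
        branch = CycleBranch(1, branch_from_fn(fn, 0, 80, n=801), branch_from_fn(fn, 0, 80, n=801, reverse=True))
        got = secant_modulus(branch, window)
        # independent oracle: continuous OLS slope by numerical quadrature
        a, b = window[0] / 100.0, window[1] / 100.0
        L = b - a
        m_e = quad(lambda x: x, a, b)[0]
        m_f = quad(fn, a, b)[0]
        m_ef = quad(lambda x: x * fn(x), a, b)[0]
        m_ee = quad(lambda x: x * x, a, b)[0]
        oracle = (m_ef - m_e * m_f / L) / (m_ee - m_e**2 / L)
        assert got == pytest.approx(oracle, rel=5e-3)

    def test_window_without_samples_raises(self):
        branch = CycleBranch(1, branch_from_fn(lambda x: x, 20, 80), branch_from_fn(lambda x: x, 20, 80, reverse=True))
        with pytest.raises(ValueError, match=r"\[0.0?, 10"):
            secant_modulus(branch, (0.0, 10.0))


class TestHysteresis:
    def test_reversible_cycle_dissipates_nothing(self):
        load = branch_from_fn(lambda x: 3.0 * x**2, 0, 80)
        cycle = CycleBranch(1, load, load[::-1])
        assert hysteresis_loss(cycle) == pytest.approx(0.0, abs=1e-12)

    def test_zero_unloading_stress_is_fully_dissipative(self):
        cycle = CycleBranch(1, branch_from_fn(lambda x: x, 0, 80), branch_from_fn(lambda x: 0.0 * x, 0, 80, reverse=True))
        assert hysteresis_loss(cycle) == pytest.approx(100.0)

    def test_linear_load_quadratic_unload_analytic_value(self):
        # A_load = 1/2, A_unload = 1/3 over strain fraction [0, 1]
        cycle = CycleBranch(
            1,
            branch_from_fn(lambda x: x, 0, 100.0, n=20001),
            branch_from_fn(lambda x: x**2, 0, 100.0, n=20001, reverse=True),
        )
        assert hysteresis_loss(cycle) == pytest.approx(100.0 * (0.5 - 1.0 / 3.0) / 0.5, rel=1e-4)

    def test_degenerate_loading_raises(self):
        flat = branch_from_fn(lambda x: 0.0 * x, 0, 80)
        with pytest.raises(ValueError):
            hysteresis_loss(CycleBranch(1, flat, flat[::-1]))

    def test_invariant_under_stress_rescaling(self):
        load = branch_from_fn(lambda x: x + 40 * x**5, 0, 80)
        unload = branch_from_fn(lambda x: 0.5 * x**2, 0, 80, reverse=True)
        h1 = hysteresis_loss(CycleBranch(1, load, unload))
        scaled = CycleBranch(1, load * [1.0, 7.0], unload * [1.0, 7.0])
        assert hysteresis_loss(scaled) == pytest.approx(h1, rel=1e-12)


class TestPlasticStrain:
    def test_elastic_return_to_origin(self):
        unload = branch_from_fn(lambda x: 5.0 * x, 0, 80, reverse=True)
        load = branch_from_fn(lambda x: 5.0 * x, 0, 80)
        ep, no_return = plastic_strain(CycleBranch(1, load, unload), baseline_tol=0.01)
        assert ep == pytest.approx(0.0, abs=0.3)
        assert not no_return

    def test_linear_unloading_root_at_30pct(self):
        sig_max = 12.0
        fn = lambda x: np.clip(sig_max * (100 * x - 30.0) / 50.0, 0.0, None)
        unload = branch_from_fn(fn, 0, 80, reverse=True)
        ep, no_return = plastic_strain(CycleBranch(1, branch_from_fn(fn, 0, 80), unload), baseline_tol=0.0)
        assert ep == pytest.approx(30.0, abs=0.05)
        assert not no_return

    def test_never_returning_stress_sets_flag(self):
        fn = lambda x: 1.0 + x
        unload = branch_from_fn(fn, 10, 80, reverse=True)
        ep, no_return = plastic_strain(CycleBranch(1, branch_from_fn(fn, 10, 80), unload))
        assert no_return
        assert ep == pytest.approx(10.0)


class TestExtractFeatures:
    def test_linear_elastic_trace_features(self):
        tr = triangular_trace(slope_kpa=2.0, area=10.0)
        feats = mech.extract_features(tr, SectionGeometry(10.0, 3.6))
        assert feats.low_strain_stiffness == pytest.approx(2.0, rel=1e-9)
        assert feats.high_strain_stiffness == pytest.approx(2.0, rel=1e-9)
        assert feats.hysteresis_loss == pytest.approx(0.0, abs=1e-9)
        assert feats.plastic_strain < 1.0  # returns to baseline near the origin
        assert len(feats.peak_stress_per_cycle) == 10

    def test_stiffness_scales_with_stress_rescaling(self):
        tr = triangular_trace(slope_kpa=2.0)
        tr2 = MechTrace(time=tr.time, strain=tr.strain, force=2.0 * tr.force)
        geom = SectionGeometry(10.0, 3.6)
        f1 = mech.extract_features(tr, geom)
        f2 = mech.extract_features(tr2, geom)
        assert f2.low_strain_stiffness == pytest.approx(2 * f1.low_strain_stiffness)
        assert f2.hysteresis_loss == pytest.approx(f1.hysteresis_loss, abs=1e-9)
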