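"""Wall adsorption: fragment weights, profiles, thresholds, zipping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import semiflex as sf
from semiflex.adsorption import contact_probability_integral


SYS = sf.AdsorptionSystem(ell=10.0, b=1.0, S=250.0)


class TestFragmentWeights:
    def test_stiff_loop_exponent(self):
        r = sf.fragment_weight(2.0, SYS, "loop") / sf.fragment_weight(1.0, SYS, "loop")
        assert r == pytest.approx(2.0 ** -2.5)

    def test_flexible_loop_exponent(self):
        r = sf.fragment_weight(400.0, SYS, "loop") / sf.fragment_weight(200.0, SYS, "loop")
        assert r == pytest.approx(2.0 ** -1.5)

    def test_tail_exponents(self):
        r_stiff = sf.fragment_weight(4.0, SYS, "tail") / sf.fragment_weight(2.0, SYS, "tail")
        r_flex = sf.fragment_weight(200.0, SYS, "tail") / sf.fragment_weight(100.0, SYS, "tail")
        assert r_stiff == pytest.approx(2.0 ** -0.25)
        assert r_flex == pytest.approx(2.0 ** -0.5)

    @given(ell=st.floats(2.0, 1e4))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_continuity_at_crossover(self, ell):
        sys_ = sf.AdsorptionSystem(ell=ell, b=1.0, S=10 * ell)
        for kind, sc in (("loop", 2 * ell), ("tail", ell)):
            lo = sf.fragment_weight(sc * (1 - 1e-12), sys_, kind)
            hi = sf.fragment_weight(sc * (1 + 1e-12), sys_, kind)
            assert hi == pytest.approx(lo, rel=1e-10)


class TestContactProbability:
    def test_boundary_values(self):
        s0 = SYS.s0
        assert sf.contact_probability(s0, SYS) == pytest.approx(1.0)
        # both middle and outer branch give (ell/s0)^(-5/2) at s = ell
        ell = SYS.ell
        assert sf.contact_probability(ell, SYS) == pytest.approx((ell / s0) ** -2.5)
        assert sf.contact_probability(ell * (1 + 1e-9), SYS) == pytest.approx(
            (ell / s0) ** -2.5, rel=1e-6
        )

    def test_stiff_exponent(self):
        s0 = SYS.s0
        assert sf.contact_probability(4 * s0, SYS) == pytest.approx(4.0 ** -2.5)

    def test_closed_form_integral(self):
        s = np.array([0.5, 2.0, 8.0, 50.0, 200.0])
        grid = np.geomspace(1e-4, 200.0, 400_001)
        P = sf.contact_probability(grid, SYS)
        from scipy.integrate import cumulative_trapezoid

        cum = cumulative_trapezoid(P, grid, initial=0.0)
        expect = np.interp(s, grid, cum) + 1e-4  # grid starts above 0
        got = contact_probability_integral(s, SYS)
        assert np.allclose(got, expect, rtol=1e-3)


@pytest.fixture(scope="module")
def loop_stats():
    return sf.sample_loop_statistics(SYS, n_chains=1_200_000, seed=123)


class TestLoopMonteCarlo:
    def test_stiff_exponent_recovered(self, loop_stats):
        assert loop_stats.stiff_slope == pytest.approx(-2.5, abs=0.2)

    def test_flexible_exponent_recovered(self, loop_stats):
        # center of the finite-chain estimate is ~ -1.42 (see methods note);
        # the asymptotic -3/2 is approached from above as S grows
        assert loop_stats.flex_slope == pytest.approx(-1.5, abs=0.3)

    def test_flexible_chain_single_regime(self):
        """Near-flexible chain: first-return statistics decay like -3/2."""
        sys_ = sf.AdsorptionSystem(ell=1.5, b=1.0, S=120.0)
        res = sf.sample_loop_statistics(sys_, n_chains=300_000, seed=5)
        assert res.flex_slope == pytest.approx(-1.5, abs=0.3)


class TestProximalProfile:
    def test_scaling_ratio(self):
        sys_ = sf.AdsorptionSystem(ell=100.0, b=1.0, S=1000.0)
        assert sf.proximal_profile(8.0, sys_) / sf.proximal_profile(4.0, sys_) == (
            pytest.approx(2.0 ** (-4.0 / 3.0))
        )

    def test_quadrature_oracle_slope(self):
        """Differentiating the cumulative loop-mass relation gives -4/3."""
        sys_ = sf.AdsorptionSystem(ell=100.0, b=1.0, S=1000.0)
        from scipy.integrate import cumulative_trapezoid

        s = np.geomspace(1.0, 100.0, 4000)
        cum = cumulative_trapezoid(s ** -2.5 * s, s, initial=0.0)
        z = sf.loop_height(s, sys_)
        c = np.gradient(cum, z)
        m = (z > 1.0) & (z < 30.0)
        slope = np.polyfit(np.log(z[m]), np.log(c[m]), 1)[0]
        assert slope == pytest.approx(-4.0 / 3.0, abs=0.013)

    def test_monte_carlo_superposition_slope(self):
        sys_ = sf.AdsorptionSystem(ell=100.0, b=1.0, S=1000.0)
        z = sf.sample_proximal_heights(sys_, n=300_000, seed=3)
        bins = np.geomspace(z.min(), z.max(), 60)
        h, e = np.histogram(z, bins=bins, density=True)
        c = np.sqrt(e[:-1] * e[1:])
        m = (c > 1.0) & (c < 30.0) & (h > 0)
        slope = np.polyfit(np.log(c[m]), np.log(h[m]), 1)[0]
        assert slope == pytest.approx(-4.0 / 3.0, abs=0.1)

    def test_out_of_range_flagged(self):
        sys_ = sf.AdsorptionSystem(ell=100.0, b=1.0, S=1000.0)
        assert np.isnan(sf.proximal_profile(1000.0, sys_))


class TestThresholds:
    def test_scaling_in_delta(self):
        a = sf.AdsorptionSystem(ell=64.0, b=1.0, S=100.0, Delta=1.0, u=10.0)
        b = sf.AdsorptionSystem(ell=64.0, b=1.0, S=100.0, Delta=8.0, u=10.0)
        assert sf.adsorption_thresholds(b)["uc"] == pytest.approx(
            sf.adsorption_thresholds(a)["uc"] / 4.0
        )

    def test_tau_zero_at_threshold(self):
        sys_ = sf.AdsorptionSystem(ell=64.0, b=1.0, S=100.0, Delta=1.0, u=1.0)
        uc = sf.adsorption_thresholds(
            sf.AdsorptionSystem(ell=64.0, b=1.0, S=100.0, Delta=1.0, u=2 * 64 ** (-1 / 3))
        )["uc"]
        at = sf.AdsorptionSystem(ell=64.0, b=1.0, S=100.0, Delta=1.0, u=uc)
        assert sf.adsorption_thresholds(at)["tau"] == pytest.approx(0.0, abs=1e-12)

    def test_not_adsorbed_below_threshold(self):
        sys_ = sf.AdsorptionSystem(ell=64.0, b=1.0, S=100.0, Delta=1.0, u=1e-3)
        assert sf.adsorption_thresholds(sys_)["regime"] == "not adsorbed"

    @given(tau_factor=st.floats(1.5, 50.0), ell=st.floats(8.0, 500.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_strong_layer_thinner_than_ell(self, tau_factor, ell):
        Delta = 0.5
        uc = (Delta**2 * ell) ** (-1 / 3)
        tau = tau_factor * (Delta / ell) ** (2 / 3)
        sys_ = sf.AdsorptionSystem(ell=ell, b=0.3, S=100.0, Delta=Delta,
                                   u=uc * (1 + tau))
        res = sf.adsorption_thresholds(sys_)
        assert res["regime"] == "strong"
        assert res["h"] < ell


class TestChemisorptionScales:
    def test_pib(self):
        s0, _ = sf.chemisorption_scales(0.59, 0.26)
        assert s0 == pytest.approx(0.34, abs=0.005)

    def test_ddna(self):
        s0, S_star = sf.chemisorption_scales(50.0, 0.34)
        assert s0 == pytest.approx(1.8, abs=0.05)
        assert S_star == pytest.approx(1.4e3, rel=0.05)

    def test_degenerate_equal_scales(self):
        s0, S_star = sf.chemisorption_scales(2.0, 2.0)
        assert s0 == pytest.approx(2.0)
        assert S_star == pytest.approx(2.0)


class TestZipping:
    def test_preemption_grows_with_chain_length(self):
        sys_ = sf.AdsorptionSystem(ell=50.0, b=1.0, S=100.0)
        short = sf.simulate_zipping(sys_, n_runs=600, seed=1, S=sys_.S_star / 20)
        long_ = sf.simulate_zipping(sys_, n_runs=600, seed=2, S=sys_.S_star * 20)
        assert short.preempt_fraction < long_.preempt_fraction
        assert long_.preempt_fraction > 0.5

    def test_preempting_loops_are_flexible_scale(self):
        sys_ = sf.AdsorptionSystem(ell=50.0, b=1.0, S=100.0)
        res = sf.simulate_zipping(sys_, n_runs=400, seed=3, S=sys_.S_star * 10)
        assert res.nucleation_sizes.size
        assert np.all(res.nucleation_sizes > sys_.ell)

    def test_crossover_near_S_star(self):
        sys_ = sf.AdsorptionSystem(ell=50.0, b=1.0, S=100.0)
        S_cross, _, fr = sf.zipping_crossover(sys_, n_runs=400, seed=4)
        assert np.isfinite(S_cross)
        assert sys_.S_star / 3 < S_cross < sys_.S_star * 3
        assert np.all(np.diff(fr) > -0.15)  # fraction rises with S


class TestCrossingStatistics:
    def test_pdf_normalized_and_median(self):
        sys_ = sf.AdsorptionSystem(ell=1000.0, b=1.0, S=100.0)
        th = np.linspace(1e-6, np.pi - 1e-6, 20001)
        res = sf.crossing_statistics(th, sys_)
        assert np.trapezoid(res["pdf"], th) == pytest.approx(1.0, abs=1e-6)
        assert sf.crossing_statistics(np.pi / 2, sys_)["cdf"] == pytest.approx(0.5)

    def test_small_angle_cumulative(self):
        sys_ = sf.AdsorptionSystem(ell=1000.0, b=1.0, S=100.0)
        assert sf.crossing_statistics(0.1, sys_)["cdf"] == pytest.approx(
            0.1**2 / 4.0, rel=1e-3
        )

    def test_alignment_probability_scaling(self):
        sys_ = sf.AdsorptionSystem(ell=1000.0, b=1.0, S=100.0)
        res = sf.crossing_statistics(0.5, sys_)
        assert res["theta_max"] == pytest.approx(0.1)
        # doubled small-angle cumulative: ~ theta_max^2 / 2
        assert res["alignment_probability"] == pytest.approx(
            (1.0 / 1000.0) ** (2 / 3) / 2.0, rel=1e-2
        )


class TestLayeredProfile:
    SYS = sf.AdsorptionSystem(ell=100.0, b=1.0, S=4000.0, c2inf=0.1)

    def test_inner_linear_growth(self):
        z1 = 1.0 / (0.1 * 1.0)
        r = sf.layered_profile(2.0, self.SYS) / sf.layered_profile(1.0, self.SYS)
        assert r == pytest.approx(2.0)

    def test_middle_inverse_square(self):
        r = sf.layered_profile(60.0, self.SYS) / sf.layered_profile(30.0, self.SYS)
        assert r == pytest.approx(0.25)

    def test_outer_inverse_linear(self):
        r = sf.layered_profile(400.0, self.SYS) / sf.layered_profile(200.0, self.SYS)
        assert r == pytest.approx(0.5)

    def test_continuity_at_boundaries(self):
        for zb in (10.0, 100.0):
            lo = sf.layered_profile(zb * (1 - 1e-10), self.SYS)
            hi = sf.layered_profile(zb * (1 + 1e-10), self.SYS)
            assert hi == pytest.approx(lo, rel=1e-8)

    def test_grafted_tail_regime_flagged(self):
        assert np.isnan(sf.layered_profile(1e4, self.SYS))
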