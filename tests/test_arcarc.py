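"""Arc/arc twist-kink gas: exact statistics vs Monte-Carlo oracles."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

import semiflex as sf
from semiflex.arcarc import partition_function_laplace, partition_function_s


FIG_PARAMS = dict(S=100.0, b=1.0, omega=0.01, ell=1000.0)


class TestKinkStatistics:
    def test_mean_one_for_caption_energy(self):
        sys_ = sf.ArcArcSystem(E_kink=-np.log(0.01), **FIG_PARAMS)
        mean, _, _ = sf.kink_statistics(sys_)
        assert mean == pytest.approx(1.0)

    def test_infinite_energy_suppresses_kinks(self):
        sys_ = sf.ArcArcSystem(E_kink=200.0, **FIG_PARAMS)
        mean, k, pmf = sf.kink_statistics(sys_)
        assert mean == pytest.approx(0.0, abs=1e-80)
        assert pmf[0] == pytest.approx(1.0)

    def test_pmf_normalized(self):
        sys_ = sf.ArcArcSystem(E_kink=2.0, **FIG_PARAMS)
        _, _, pmf = sf.kink_statistics(sys_)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)


class TestDeflectionPdf:
    @pytest.mark.parametrize("E", [4.0, 6.0, 8.0])
    @pytest.mark.parametrize("flex", [False, True])
    def test_normalization(self, E, flex):
        sys_ = sf.ArcArcSystem(E_kink=E, **FIG_PARAMS)
        dist = sf.deflection_pdf(sys_, with_flexure=flex)
        assert dist.total_mass() == pytest.approx(1.0, abs=1e-8)

    def test_atom_weight(self):
        sys_ = sf.ArcArcSystem(E_kink=4.0, **FIG_PARAMS)
        dist = sf.deflection_pdf(sys_)
        assert dist.atom_weight == pytest.approx(
            np.exp(-sys_.mean_kinks) / 2.0
        )

    def test_even_and_compact_support(self):
        sys_ = sf.ArcArcSystem(E_kink=5.0, **FIG_PARAMS)
        dist = sf.deflection_pdf(sys_)
        assert np.allclose(dist.density, dist.density[::-1], rtol=1e-10)
        assert dist.theta_grid[0] > -dist.support
        assert dist.theta_grid[-1] < dist.support

    @pytest.mark.parametrize("E", [4.0, 6.0])
    def test_matches_monte_carlo_ks(self, E):
        sys_ = sf.ArcArcSystem(E_kink=E, **FIG_PARAMS)
        dist = sf.deflection_pdf(sys_, with_flexure=True)
        theta = sf.sample_deflection_angles(sys_, 100_000, seed=int(E))
        ks = kstest(theta, dist.cdf)
        assert ks.statistic < 0.01

    def test_second_moment_matches_sampler(self):
        sys_ = sf.ArcArcSystem(E_kink=4.0, **FIG_PARAMS)
        dist = sf.deflection_pdf(sys_, with_flexure=True)
        theta = sf.sample_deflection_angles(sys_, 100_000, seed=9)
        se = np.std(theta**2, ddof=1) / np.sqrt(len(theta))
        assert abs(np.mean(theta**2) - dist.moment(2)) < 3 * se


class TestCorrelation:
    def test_C0_is_one(self):
        sys_ = sf.ArcArcSystem(E_kink=3.0, **FIG_PARAMS)
        s, C, _, _ = sf.correlation_and_moments(sys_)
        assert C[0] == pytest.approx(1.0, abs=1e-12)

    def test_wlc_limit_small_omega(self):
        sys_ = sf.ArcArcSystem(S=100.0, b=1.0, omega=1e-13, ell=1000.0, E_kink=4.0)
        s, C, _, _ = sf.correlation_and_moments(sys_)
        assert np.max(np.abs(C - np.exp(-s / 2000.0))) < 1e-10

    def test_damped_cosine_limit_large_E(self):
        sys_ = sf.ArcArcSystem(S=100.0, b=1.0, omega=0.1, ell=1000.0, E_kink=35.0)
        s, C, _, _ = sf.correlation_and_moments(sys_)
        expect = np.exp(-s / 2000.0) * np.cos(0.1 * s)
        assert np.max(np.abs(C - expect)) < 1e-10

    def test_oscillatory_iff_turn_survives(self):
        # omega b e^E > 1: oscillatory (C goes negative)
        osc = sf.ArcArcSystem(S=600.0, b=1.0, omega=0.05, ell=1000.0, E_kink=5.0)
        s, C, _, _ = sf.correlation_and_moments(osc, s=np.linspace(0, 600, 2001))
        assert C.min() < -0.01
        # omega b e^E < 1: monotone decay
        mono = sf.ArcArcSystem(S=600.0, b=1.0, omega=0.05, ell=1000.0, E_kink=1.0)
        s2, C2, _, _ = sf.correlation_and_moments(mono, s=np.linspace(0, 600, 2001))
        assert np.all(np.diff(C2) < 1e-12)
        assert C2.min() > -1e-9


class TestMoments:
    @pytest.mark.parametrize("E", [2.0, 6.0, 10.0])
    def test_rg2_matches_double_integration(self, E):
        """Closed-form Rg2 equals direct integration of C(s)."""
        sys_ = sf.ArcArcSystem(E_kink=E, **FIG_PARAMS)
        _, _, re2, rg2 = sf.correlation_and_moments(sys_)
        S = sys_.S
        u = np.linspace(0, S, 40001)
        _, Cu, _, _ = sf.correlation_and_moments(sys_, s=u)
        from scipy.integrate import cumulative_trapezoid

        inner = cumulative_trapezoid(Cu, u, initial=0.0)
        re2_of_u = 2.0 * (u * inner - cumulative_trapezoid(u * Cu, u, initial=0.0))
        re2_num = re2_of_u[-1]
        rg2_num = np.trapezoid((S - u) * re2_of_u, u) / S**2
        assert re2 == pytest.approx(re2_num, rel=1e-6)
        assert rg2 == pytest.approx(rg2_num, rel=1e-6)

    def test_moments_match_sampler(self):
        sys_ = sf.ArcArcSystem(E_kink=6.0, **FIG_PARAMS)
        _, _, re2, rg2 = sf.correlation_and_moments(sys_)
        ens = sf.sample_chain(sys_, 4000, seed=5)
        e = ens.end_to_end_sq()
        g = ens.gyration_sq()
        for sample, closed in ((e, re2), (g, rg2)):
            se = sample.std(ddof=1) / np.sqrt(len(sample))
            assert abs(sample.mean() - closed) < 3 * se

    def test_undulations_only_above_caption_energy(self):
        """Rg2(S) undulates (wiggling log-log slope) when kinks are too
        rare to destroy a turn, and is monotone-smooth otherwise."""
        omega, b = 0.01, 1.0
        E_star = -np.log(b * omega)
        Ss = np.geomspace(100, 6000, 200)

        def slope_extrema(E):
            rg = np.array(
                [
                    sf.correlation_and_moments(
                        sf.ArcArcSystem(S=S, b=b, omega=omega, ell=1000.0, E_kink=E),
                        s=np.array([0.0]),
                    )[3]
                    for S in Ss
                ]
            )
            g = np.gradient(np.log(rg), np.log(Ss))
            return int(np.sum(np.diff(np.sign(np.diff(g))) != 0))

        assert slope_extrema(E_star + 2.0) >= 2  # undulating
        assert slope_extrema(E_star - 2.0) == 0  # monotone-smooth


class TestLaplaceDomain:
    @pytest.mark.parametrize("q", [0.3, 1.0, 2.5])
    @pytest.mark.parametrize("p", [0.5, 1.2])
    def test_transform_of_s_domain_partition_function(self, q, p):
        sys_ = sf.ArcArcSystem(S=100.0, b=1.0, omega=0.05, ell=1000.0, E_kink=2.0)
        expect = complex(partition_function_laplace(sys_, q, p))
        a = np.exp(-sys_.E_kink)
        r = np.sqrt(complex(a**2 - q**2 * sys_.omega**2 * sys_.b**2))

        def damped(n):
            # e^{-pn} Z(q, n) with the damping folded in (overflow-safe)
            return ((r + a) * np.exp((r - p) * n)
                    + (r - a) * np.exp(-(r + p) * n)) / (2.0 * r)

        re = quad(lambda n: np.real(damped(n)), 0, np.inf, limit=400)[0]
        im = quad(lambda n: np.imag(damped(n)), 0, np.inf, limit=400)[0]
        assert complex(re, im) == pytest.approx(expect, rel=1e-6, abs=1e-9)


class TestSampler:
    def test_no_kinks_gives_circular_arc(self):
        sys_ = sf.ArcArcSystem(S=100.0, b=1.0, omega=0.02, ell=1000.0, E_kink=300.0)
        ens = sf.sample_chain(sys_, 50, seed=2, with_flexure=False)
        dth = np.diff(ens.theta, axis=1)
        for row in dth:
            assert np.allclose(np.abs(row), 0.02, atol=1e-9)
            assert np.all(np.sign(row) == np.sign(row[0]))  # never flips

    def test_deflection_symmetric_zero_mean(self):
        sys_ = sf.ArcArcSystem(E_kink=4.0, **FIG_PARAMS)
        theta = sf.sample_deflection_angles(sys_, 200_000, seed=8)
        se = theta.std(ddof=1) / np.sqrt(len(theta))
        assert abs(theta.mean()) < 3 * se
        # symmetry: compare upper and lower tail masses
        q = np.quantile(np.abs(theta), 0.9)
        assert abs(np.mean(theta > q) - np.mean(theta < -q)) < 0.005


class TestLinearExtension:
    def test_zero_force(self):
        sys_ = sf.ArcArcSystem(E_kink=4.0, **FIG_PARAMS)
        assert sf.linear_extension(sys_, 0.0) == 0.0

    def test_linearity_and_re2_insertion(self):
        sys_ = sf.ArcArcSystem(E_kink=4.0, **FIG_PARAMS)
        _, _, re2, _ = sf.correlation_and_moments(sys_)
        x1 = sf.linear_extension(sys_, 0.01)
        x2 = sf.linear_extension(sys_, 0.02)
        assert x2 == pytest.approx(2 * x1)
        assert x1 == pytest.approx(re2 * 0.01 / 2.0)
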