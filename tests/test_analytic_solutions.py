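import numpy as np
import pytest
from scipy import integrate

from noisygrowth import (
    InvalidInputError,
    LinearModelParams,
    LinearSolution,
    LogisticModelParams,
    LogisticSolution,
    NoiseParams,
    UndefinedLimitError,
    alpha,
    beta_of,
    gamma_sq,
    linear_moments,
    linear_pdf,
    local_growth_rate_chi,
    logistic_mean,
    logistic_pdf,
    map_stationary_beta,
    mean_growth_rate,
    mean_limits,
    numeric_chi,
    stationary_beta_params,
    z_var,
)
from noisygrowth.analytic_solutions import (
    A_of,
    linear_dispersion_approx,
    normalization,
)


def nested_gamma_sq_oracle(t, D, tau_c):
    """Brute-force nested quadrature of the autocovariance over [0, t]^2."""

    def inner(t1):
        val, _ = integrate.quad(lambda u: np.exp(-u / tau_c), 0, t1, limit=200)
        return val

    outer, _ = integrate.quad(inner, 0, t, limit=200)
    return 2.0 * D * outer


def nested_z_var_oracle(t, D, tau_c, gamma):
    """Brute-force nested quadrature of the exponentially weighted autocovariance."""
    lam = 1.0 / tau_c

    def inner(t1):
        val, _ = integrate.quad(lambda u: np.exp(-u * (gamma + lam)), 0, t1, limit=200)
        return np.exp(-2.0 * gamma * (t - t1)) * val

    outer, _ = integrate.quad(inner, 0, t, limit=200)
    return 2.0 * D * outer


def quad_over_decades(func, lo=1e-9, hi=1e9):
    edges = np.geomspace(lo, hi, 19)
    return sum(
        integrate.quad(func, a, b, limit=100)[0] for a, b in zip(edges[:-1], edges[1:])
    )


class TestGammaSq:
    def test_zero_at_t0(self, ou_unit):
        assert gamma_sq(0.0, ou_unit) == 0.0

    def test_small_t_quadratic(self, ou_unit):
        # t << tau_c: <Gamma^2> ~ D t^2
        t = 1e-4
        assert gamma_sq(t, ou_unit) == pytest.approx(ou_unit.D * t * t, rel=1e-3)

    @pytest.mark.parametrize("d,tau", [(1.0, 1.0), (4.0, 0.5), (100.0, 0.01)])
    @pytest.mark.parametrize("t", [0.1, 1.0, 5.0])
    def test_matches_nested_quadrature(self, d, tau, t):
        noise = NoiseParams(D=d, tau_c=tau)
        oracle = nested_gamma_sq_oracle(t, d, tau)
        assert gamma_sq(t, noise) == pytest.approx(oracle, rel=1e-8)

    def test_rejects_negative_time(self, ou_unit):
        with pytest.raises(InvalidInputError):
            gamma_sq(-0.1, ou_unit)


class TestAlpha:
    def test_consistent_with_gamma_sq(self, ou_unit):
        for t in (0.2, 1.0, 3.0):
            assert 2.0 * alpha(t, ou_unit) * t == pytest.approx(gamma_sq(t, ou_unit))

    def test_monotone_increase_to_plateau(self, ou_unit):
        ts = np.linspace(0.01, 50, 400)
        vals = alpha(ts, ou_unit)
        assert np.all(np.diff(vals) > 0)
        assert np.all(vals < ou_unit.D * ou_unit.tau_c)
        assert vals[-1] == pytest.approx(ou_unit.D * ou_unit.tau_c, rel=0.03)

    def test_short_correlation_time_limit(self):
        # tau_c -> 0 at fixed D tau_c = 1: alpha -> 1
        noise = NoiseParams(D=1e4, tau_c=1e-4)
        assert alpha(1.0, noise) == pytest.approx(1.0, rel=1e-3)


class TestLinearPdf:
    def test_normalized_and_mean_consistent(self, ou_unit):
        p = LinearModelParams(C0=1.0, noise=ou_unit)
        t = 1.0
        total = quad_over_decades(lambda c: linear_pdf(c, t, p))
        assert total == pytest.approx(1.0, abs=1e-9)
        mean_quad = quad_over_decades(lambda c: c * linear_pdf(c, t, p))
        mean_closed, _ = linear_moments(t, p)
        assert mean_quad == pytest.approx(mean_closed, rel=1e-6)

    def test_dispersion_identity(self, ou_unit):
        # (dispersion/mean)^2 + 1 = e^{2 alpha t} for any t
        p = LinearModelParams(C0=2.0, noise=ou_unit)
        for t in (0.3, 1.0, 2.5):
            mean, disp = linear_moments(t, p)
            assert (disp / mean) ** 2 + 1 == pytest.approx(
                np.exp(2.0 * alpha(t, ou_unit) * t), rel=1e-12
            )

    def test_variance_matches_quadrature(self, ou_unit):
        p = LinearModelParams(C0=1.0, noise=ou_unit)
        t = 0.8
        m2 = quad_over_decades(lambda c: c * c * linear_pdf(c, t, p))
        mean, disp = linear_moments(t, p)
        assert np.sqrt(m2 - mean**2) == pytest.approx(disp, rel=1e-6)

    def test_constant_drift_shifts_location(self, ou_unit):
        p = LinearModelParams(C0=1.0, gamma_const=0.7, noise=ou_unit)
        p0 = LinearModelParams(C0=1.0, noise=ou_unit)
        t, c = 1.3, 2.0
        shifted = linear_pdf(c, t, p)
        base = linear_pdf(c * np.exp(-0.7 * t), t, p0) * np.exp(-0.7 * t)
        assert shifted == pytest.approx(base, rel=1e-12)

    def test_negative_drift_mean_grows_while_mode_shrinks(self):
        # |gamma_const| < alpha_inf: mean grows but the density mode decays
        noise = NoiseParams(D=100.0, tau_c=0.01)  # alpha_inf ~ 1
        p = LinearModelParams(C0=1.0, gamma_const=-0.5, noise=noise)
        ts = np.array([2.0, 4.0, 8.0])
        means = linear_moments(ts, p)[0]
        assert np.all(np.diff(means) > 0)
        # log-normal mode: C0 exp((gamma - 2 alpha) t)
        modes = np.exp((-0.5 - 2.0 * alpha(ts, noise)) * ts)
        assert np.all(np.diff(modes) < 0)

    def test_rejects_nonpositive_population(self, ou_unit):
        p = LinearModelParams(C0=1.0, noise=ou_unit)
        with pytest.raises(InvalidInputError):
            linear_pdf(-1.0, 1.0, p)


class TestZVar:
    def test_zero_at_t0(self, logistic_short_memory):
        assert z_var(0.0, logistic_short_memory) == pytest.approx(0.0, abs=1e-12)
        assert beta_of(0.0, logistic_short_memory) == np.inf

    def test_large_t_limit(self, logistic_short_memory):
        # D / (gamma (gamma + 1/tau_c)) with D=100, gamma=1, tau_c=0.01
        assert z_var(50.0, logistic_short_memory) == pytest.approx(100.0 / 101.0, rel=1e-9)

    @pytest.mark.parametrize(
        "d,tau,g", [(1.0, 1.0, 1.0), (100.0, 0.01, 1.0), (4.0, 2.0, 0.5)]
    )
    @pytest.mark.parametrize("t", [0.1, 1.0, 5.0])
    def test_matches_nested_quadrature(self, d, tau, g, t):
        p = LogisticModelParams(C0=1.0, gamma=g, epsilon=0.5,
                                noise=NoiseParams(D=d, tau_c=tau))
        assert z_var(t, p) == pytest.approx(nested_z_var_oracle(t, d, tau, g), rel=1e-7)

    def test_removable_singularity_branch(self):
        # gamma tau_c = 1 exactly: limit expression must agree with the oracle
        p = LogisticModelParams(C0=1.0, gamma=1.0, epsilon=0.5,
                                noise=NoiseParams(D=2.0, tau_c=1.0))
        for t in (0.1, 1.0, 5.0):
            assert z_var(t, p) == pytest.approx(nested_z_var_oracle(t, 2.0, 1.0, 1.0),
                                                rel=1e-7)

    def test_branch_continuity_near_singularity(self):
        near = LogisticModelParams(C0=1.0, gamma=1.0, epsilon=0.5,
                                   noise=NoiseParams(D=2.0, tau_c=1.0 + 2e-5))
        at = LogisticModelParams(C0=1.0, gamma=1.0, epsilon=0.5,
                                 noise=NoiseParams(D=2.0, tau_c=1.0))
        assert z_var(1.0, near) == pytest.approx(z_var(1.0, at), rel=1e-4)


class TestStationaryBetaMapping:
    def test_round_trip(self):
        for beta_star in (5.0, 50.0, 500.0):
            p = stationary_beta_params(beta_star, 1.0, 0.5, 0.01)
            assert beta_of(1e4, p) == pytest.approx(beta_star, rel=1e-9)

    def test_known_value(self):
        # gamma=1, tau_c=0.01, beta*=500 -> D = 101/1000
        assert map_stationary_beta(500.0, 1.0, 0.01) == pytest.approx(0.101)

    def test_monotone(self):
        ds = [map_stationary_beta(b, 1.0, 0.01) for b in (5.0, 50.0, 500.0)]
        assert ds == sorted(ds, reverse=True)


class TestLogisticPdf:
    def test_normalized_on_fig_parameter_sets(self, fig_like_logistic_sets):
        for p in fig_like_logistic_sets:
            for t in (0.4, 2.0, 4.0):
                total = quad_over_decades(lambda c: logistic_pdf(c, t, p))
                assert total == pytest.approx(1.0, abs=1e-6)

    def test_erfc_normalization_matches_quadrature(self, fig_like_logistic_sets):
        p = fig_like_logistic_sets[1]
        t = 1.0
        beta = beta_of(t, p)
        A = A_of(t, p)
        n_quad = 1.0 / integrate.quad(lambda z: np.exp(-beta * z * z), -A, 40.0)[0]
        assert normalization(t, p, beta) == pytest.approx(n_quad, rel=1e-9)

    def test_large_beta_concentrates_on_deterministic_solution(self):
        p = stationary_beta_params(1e6, 1.0, 0.5, 0.01)
        t = 1.5
        c_grid = np.linspace(0.5, 3.0, 2501)
        dens = logistic_pdf(c_grid, t, p)
        mode = c_grid[np.argmax(dens)]
        deterministic = 1.0 / A_of(t, p)
        assert mode == pytest.approx(deterministic, rel=1e-3)

    def test_mode_near_carrying_capacity_at_t4(self, fig_like_logistic_sets):
        p = fig_like_logistic_sets[0]  # beta* = 500, C* = 2
        c_grid = np.linspace(0.5, 4.0, 2001)
        dens = logistic_pdf(c_grid, 4.0, p)
        assert c_grid[np.argmax(dens)] == pytest.approx(2.0, abs=0.1)

    def test_stationary_beta_mode(self, fig_like_logistic_sets):
        p = fig_like_logistic_sets[1]
        val = logistic_pdf(2.0, 0.4, p, mode="stationary_beta", beta_star=50.0)
        assert val > 0
        with pytest.raises(InvalidInputError):
            logistic_pdf(2.0, 0.4, p, mode="stationary_beta")

    def test_rejects_bad_inputs(self, fig_like_logistic_sets):
        p = fig_like_logistic_sets[0]
        with pytest.raises(InvalidInputError):
            logistic_pdf(-1.0, 1.0, p)
        with pytest.raises(InvalidInputError):
            logistic_pdf(1.0, 0.0, p)


class TestLogisticMean:
    def test_large_beta_limit_is_carrying_capacity(self, fig_like_logistic_sets):
        report = mean_limits(fig_like_logistic_sets[0])
        assert report.large_beta_limit == 2.0

    def test_quadrature_mean_near_capacity(self, fig_like_logistic_sets):
        mean = logistic_mean(10.0, fig_like_logistic_sets[0])
        assert mean == pytest.approx(2.0, rel=0.02)

    def test_undefined_limit_for_zero_epsilon(self, ou_unit):
        p = LogisticModelParams(C0=1.0, gamma=1.0, epsilon=0.0, noise=ou_unit)
        with pytest.raises(UndefinedLimitError):
            mean_limits(p)

    def test_small_beta_mean_grows_as_epsilon_shrinks(self):
        p = LogisticModelParams(C0=1.0, gamma=0.5, epsilon=0.5,
                                noise=NoiseParams(D=1.0, tau_c=0.01))
        report = mean_limits(p, small_beta=0.05, eps_grid=(0.5, 0.1, 0.02))
        means = report.small_beta_means
        assert all(b > a for a, b in zip(means, means[1:]))
        assert report.diverges_logarithmically


class TestGrowthRate:
    def test_stationary_at_large_time(self, fig_like_logistic_sets):
        grid = np.linspace(0.1, 10.0, 100)
        chi_late = local_growth_rate_chi(grid, 14.0, fig_like_logistic_sets[1])
        assert np.abs(chi_late.chi).max() < 1e-3

    def test_decreasing_before_first_zero_crossing(self, fig_like_logistic_sets):
        # the positive branch at small populations falls off with population size
        for p in fig_like_logistic_sets:
            cstar = p.gamma / p.epsilon
            grid = np.linspace(0.05 * cstar, cstar, 400)
            chi = local_growth_rate_chi(grid, 0.8, p).chi
            first_neg = np.argmax(chi < 0)
            assert first_neg > 10  # a visible positive branch exists
            assert np.all(np.diff(chi[:first_neg]) < 0)

    def test_zero_crossings_match_numeric_oracle(self, fig_like_logistic_sets):
        def crossings(grid, y):
            sign_change = np.diff(np.sign(y)) != 0
            return grid[:-1][sign_change]

        for p in fig_like_logistic_sets[1:]:  # beta* = 50 and 5
            for t in (0.4, 0.8):
                grid = np.linspace(0.3, 6.0, 1500)
                closed = local_growth_rate_chi(grid, t, p).chi
                numeric = numeric_chi(grid, t, p).chi
                c_closed = crossings(grid, closed)
                c_numeric = crossings(grid, numeric)
                assert len(c_closed) == len(c_numeric)
                np.testing.assert_allclose(c_closed, c_numeric, atol=0.05)
                agree = np.mean(np.sign(closed) == np.sign(numeric))
                assert agree > 0.99

    def test_mean_growth_rate_relaxes_to_zero(self, fig_like_logistic_sets):
        p = fig_like_logistic_sets[0]
        early = mean_growth_rate(0.5, p)
        late = mean_growth_rate(10.0, p)
        assert early > 0.1
        assert abs(late) < 1e-3

    def test_rejects_underflowing_time(self, fig_like_logistic_sets):
        with pytest.raises(InvalidInputError):
            local_growth_rate_chi(np.array([1.0]), 1e-300, fig_like_logistic_sets[0])


class TestSolutionFacades:
    def test_linear_solution_consistency(self, ou_unit):
        sol = LinearSolution(LinearModelParams(C0=1.0, noise=ou_unit))
        t = 1.2
        assert sol.mean(t) == pytest.approx(np.exp(sol.alpha(t) * t))
        assert sol.dispersion(t) < sol.dispersion(t, approx=True)
        assert sol.cdf(1e9, t) == pytest.approx(1.0)

    def test_logistic_solution_modes(self, fig_like_logistic_sets):
        p = fig_like_logistic_sets[1]
        td = LogisticSolution(p)
        sb = LogisticSolution(p, mode="stationary_beta", beta_star=50.0)
        assert td.beta(0.4) > sb.beta(0.4)  # beta(t) decays toward beta*
        assert td.beta(20.0) == pytest.approx(50.0, rel=1e-4)
        assert sb.pdf(2.0, 4.0) == pytest.approx(td.pdf(2.0, 4.0), rel=0.05)

    def test_adjustable_variance_construction(self):
        # same mean growth, reduced dispersion growth: gamma_L = 0.99 alpha,
        # alpha_L = 0.01 alpha built by scaling D at fixed tau_c
        base = NoiseParams(D=100.0, tau_c=0.01)   # alpha_inf = 1
        reduced = NoiseParams(D=1.0, tau_c=0.01)  # alpha_inf = 0.01
        p_full = LinearModelParams(C0=1.0, noise=base)
        p_reduced = LinearModelParams(C0=1.0, gamma_const=0.99, noise=reduced)
        t = 30.0
        m_full, _ = linear_moments(t, p_full)
        m_red, _ = linear_moments(t, p_reduced)
        assert np.log(m_red) / np.log(m_full) == pytest.approx(1.0, rel=1e-3)
        assert linear_dispersion_approx(t, p_reduced) < linear_dispersion_approx(t, p_full)
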