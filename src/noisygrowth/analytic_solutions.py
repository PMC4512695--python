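"""Closed-form time-dependent solutions of the growth models.

Linear model
------------
With ``Gamma(t)`` the integrated noise, ``ln(C/C0) = gamma_const * t + Gamma``
is Gaussian, so the population is log-normal with scale

    <Gamma^2>(t) = 2 D tau_c [ t - tau_c (1 - e^{-t/tau_c}) ]  =  2 alpha(t) t,

and moments  <C> = C0 e^{(gamma_const + alpha) t},
dispersion  DC = C0 e^{gamma_const t} sqrt(e^{4 alpha t} - e^{2 alpha t})
(the widely quoted large-scale approximation  DC ~ C0 e^{(gamma_const + 2 alpha) t}
is exposed separately).

Logistic model
--------------
In the reciprocal variable ``y = 1/C`` the dynamics are linear, so
``z = y - A(t)`` is Gaussian with

    A(t)    = e^{-gamma t}/C0 + (epsilon/gamma)(1 - e^{-gamma t}),
    <z^2>(t)= (D/gamma) [ 1/(gamma+lam)
              - 2 gamma e^{-(gamma+lam)t} / (gamma^2 - lam^2)
              + e^{-2 gamma t} / (gamma - lam) ],     lam = 1/tau_c,

(with the removable singularity at gamma * tau_c = 1 evaluated by its limit)
and the population density is the mapped truncated Gaussian

    P(C) = N / C^2 * exp(-beta (1/C - A)^2),    beta = 1 / (2 <z^2>),

normalized over C in (0, inf), i.e. ``1/N = integral_{-A}^{inf} e^{-beta z^2} dz``
(complementary-error-function form, stable at large beta).

``beta`` modes: the default ``"time_dependent"`` mode evaluates beta(t) from
the noise parameters; ``"stationary_beta"`` holds beta fixed at a quoted value
(the convention used when a single beta is attached to a whole density
sequence; the quoted value equals the t -> inf limit of beta(t), see
:func:`map_stationary_beta`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from scipy.special import erfc

from .colored_noise import NoiseParams
from .errors import InvalidInputError, UndefinedLimitError
from .sde_models import LinearModelParams, LogisticModelParams

__all__ = [
    "gamma_sq",
    "alpha",
    "linear_pdf",
    "linear_cdf",
    "linear_moments",
    "linear_dispersion_approx",
    "z_var",
    "beta_of",
    "map_stationary_beta",
    "stationary_beta_params",
    "A_of",
    "normalization",
    "logistic_pdf",
    "logistic_cdf",
    "logistic_mean",
    "mean_limits",
    "MeanLimitReport",
    "local_growth_rate_chi",
    "numeric_chi",
    "mean_growth_rate",
    "GrowthRateProfile",
    "LinearSolution",
    "LogisticSolution",
]

_MODES = ("time_dependent", "stationary_beta")


def _check_t(t, allow_zero=True):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or (not allow_zero and np.any(t == 0)):
        cmp = ">=" if allow_zero else ">"
        raise InvalidInputError(f"time must be {cmp} 0")
    return t


# ----------------------------------------------------------------- linear model

def gamma_sq(t, noise: NoiseParams):
    """Variance of the integrated noise: 2 D tau_c [t - tau_c (1 - e^{-t/tau_c})]."""
    t = _check_t(t)
    tau = noise.tau_c
    # clamp: the subtraction cancels to ~t*eps for t << tau and can go negative
    return np.maximum(2.0 * noise.D * tau * (t - tau * (-np.expm1(-t / tau))), 0.0)


def alpha(t, noise: NoiseParams):
    """Time-varying exponential growth rate, ``<Gamma^2> / (2 t)``; 0 at t = 0.

    Increases monotonically from 0 toward its short-correlation-time plateau
    ``D * tau_c``.
    """
    t = _check_t(t)
    tau = noise.tau_c
    with np.errstate(divide="ignore", invalid="ignore"):
        out = noise.D * tau * (1.0 - tau / t * (-np.expm1(-t / tau)))
    return np.where(t == 0, 0.0, out) if np.ndim(t) else (0.0 if t == 0 else float(out))


def _linear_dist(t, params: LinearModelParams):
    t = float(_check_t(t, allow_zero=False))
    s2 = gamma_sq(t, params.noise)
    if s2 <= 0:
        raise InvalidInputError("density is degenerate (zero noise variance)")
    scale = params.C0 * np.exp(params.gamma_const * t)
    return stats.lognorm(s=np.sqrt(s2), scale=scale)


def linear_pdf(c, t, params: LinearModelParams):
    """Log-normal population density of the linear model at time ``t > 0``."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise InvalidInputError("population values must be > 0")
    return _linear_dist(t, params).pdf(c)


def linear_cdf(c, t, params: LinearModelParams):
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise InvalidInputError("population values must be > 0")
    return _linear_dist(t, params).cdf(c)


def linear_moments(t, params: LinearModelParams):
    """Exact mean and dispersion (std) of the linear model at time ``t``.

    mean = C0 e^{(gamma_const + alpha) t};
    dispersion = C0 e^{gamma_const t} sqrt(e^{4 alpha t} - e^{2 alpha t}).
    """
    t = _check_t(t)
    at = alpha(t, params.noise) * t
    drift = np.exp(params.gamma_const * t)
    mean = params.C0 * drift * np.exp(at)
    disp = params.C0 * drift * np.sqrt(np.exp(4.0 * at) - np.exp(2.0 * at))
    return mean, disp


def linear_dispersion_approx(t, params: LinearModelParams):
    """Large-spread approximation ``C0 e^{(gamma_const + 2 alpha) t}`` of the dispersion."""
    t = _check_t(t)
    at = alpha(t, params.noise) * t
    return params.C0 * np.exp(params.gamma_const * t + 2.0 * at)


# --------------------------------------------------------------- logistic model

_SINGULAR_TOL = 1e-6


def z_var(t, params: LogisticModelParams):
    """Variance of the reciprocal-population fluctuation ``z`` at time ``t``.

    Evaluates the closed double-integral form; the removable singularity at
    ``gamma * tau_c = 1`` is handled by its l'Hopital limit
    ``(D / 2 gamma^2) [1 - (1 + 2 gamma t) e^{-2 gamma t}]`` with a relative
    switch at 1e-6.
    """
    t = _check_t(t)
    g = params.gamma
    D = params.noise.D
    lam = 1.0 / params.noise.tau_c
    if abs(g * params.noise.tau_c - 1.0) < _SINGULAR_TOL:
        out = (D / (2.0 * g * g)) * (1.0 - (1.0 + 2.0 * g * t) * np.exp(-2.0 * g * t))
    else:
        out = (D / g) * (
            1.0 / (g + lam)
            - (2.0 * g / (g * g - lam * lam)) * np.exp(-(g + lam) * t)
            + np.exp(-2.0 * g * t) / (g - lam)
        )
    return np.maximum(out, 0.0)  # clamp round-off negatives near t = 0


def beta_of(t, params: LogisticModelParams):
    """Inverse-variance coefficient ``beta = 1 / (2 <z^2>)``; infinite at t = 0."""
    zv = np.asarray(z_var(t, params), dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(zv > 0, 0.5 / np.where(zv > 0, zv, 1.0), np.inf)
    return out if zv.ndim else float(out)


def map_stationary_beta(beta_star: float, gamma: float, tau_c: float) -> float:
    """Noise magnitude ``D`` whose stationary (t -> inf) beta equals ``beta_star``:
    ``D = gamma (gamma + 1/tau_c) / (2 beta_star)``."""
    if beta_star <= 0:
        raise InvalidInputError(f"beta_star must be > 0, got {beta_star}")
    return gamma * (gamma + 1.0 / tau_c) / (2.0 * beta_star)


def stationary_beta_params(
    beta_star: float, gamma: float, epsilon: float, tau_c: float, C0: float = 1.0
) -> LogisticModelParams:
    """Logistic parameters whose noise magnitude realizes the quoted stationary beta."""
    D = map_stationary_beta(beta_star, gamma, tau_c)
    return LogisticModelParams(C0=C0, gamma=gamma, epsilon=epsilon,
                               noise=NoiseParams(D=D, tau_c=tau_c))


def A_of(t, params: LogisticModelParams):
    """Deterministic reciprocal path ``A(t) = e^{-gamma t}/C0 + (eps/gamma)(1 - e^{-gamma t})``."""
    t = _check_t(t)
    g = params.gamma
    e = np.exp(-g * t)
    return e / params.C0 + (params.epsilon / g) * (1.0 - e)


def _resolve_beta(t, params, mode, beta_star):
    if mode not in _MODES:
        raise InvalidInputError(f"mode must be one of {_MODES}, got {mode!r}")
    if mode == "stationary_beta":
        if beta_star is None or beta_star <= 0:
            raise InvalidInputError("stationary_beta mode requires beta_star > 0")
        return float(beta_star)
    return float(beta_of(t, params))


def normalization(t, params: LogisticModelParams, beta: float):
    """Normalization constant ``N`` of the mapped truncated Gaussian.

    ``1/N = integral_{-A}^{inf} e^{-beta z^2} dz = sqrt(pi / beta) / 2 *
    erfc(-A sqrt(beta))``; the erfc form stays finite and accurate at large beta.
    """
    A = A_of(t, params)
    n_inv = 0.5 * np.sqrt(np.pi / beta) * erfc(-A * np.sqrt(beta))
    return 1.0 / n_inv


def logistic_pdf(c, t, params: LogisticModelParams, mode: str = "time_dependent",
                 beta_star: float | None = None):
    """Population density of the reduced logistic model at ``t > 0``."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise InvalidInputError("population values must be > 0")
    t = float(_check_t(t, allow_zero=False))
    beta = _resolve_beta(t, params, mode, beta_star)
    if not np.isfinite(beta):
        raise InvalidInputError("beta is infinite (degenerate density); need t > 0 and D > 0")
    A = A_of(t, params)
    N = normalization(t, params, beta)
    z = 1.0 / c - A
    return N / (c * c) * np.exp(-beta * z * z)


def logistic_cdf(c, t, params: LogisticModelParams, mode: str = "time_dependent",
                 beta_star: float | None = None):
    """CDF of the logistic-model density (conditional on the population being finite).

    ``P(C <= c) = erfc((1/c - A) sqrt(beta)) / erfc(-A sqrt(beta))``.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise InvalidInputError("population values must be > 0")
    t = float(_check_t(t, allow_zero=False))
    beta = _resolve_beta(t, params, mode, beta_star)
    A = A_of(t, params)
    rb = np.sqrt(beta)
    return erfc((1.0 / c - A) * rb) / erfc(-A * rb)


def logistic_mean(t, params: LogisticModelParams, mode: str = "time_dependent",
                  beta_star: float | None = None, cmax: float | None = None):
    """Mean population by quadrature against the logistic density.

    Integration runs in the reciprocal fluctuation ``z = 1/C - A`` where the
    density is a truncated Gaussian, over ``z`` in
    ``[max(-A + 1/cmax, -8 sigma), 8 sigma]`` with ``sigma = 1/sqrt(2 beta)``.
    The population cutoff ``cmax`` (default ``1e6 * max(C_*, C0)``) regularizes
    the logarithmic large-population divergence that appears once the Gaussian
    reaches ``z = -A``; at large beta the 8-sigma window never gets there and
    the cutoff is inert.
    """
    t = float(_check_t(t, allow_zero=False))
    beta = _resolve_beta(t, params, mode, beta_star)
    A = float(A_of(t, params))
    if cmax is None:
        ceiling = params.gamma / params.epsilon if params.epsilon > 0 else 1.0
        cmax = 1e6 * max(ceiling, params.C0)
    sigma = 1.0 / np.sqrt(2.0 * beta)
    N = normalization(t, params, beta)
    lo = max(-A + 1.0 / cmax, -8.0 * sigma)
    hi = 8.0 * sigma
    val, _ = integrate.quad(lambda z: N * np.exp(-beta * z * z) / (A + z), lo, hi,
                            limit=200)
    return val


@dataclass(frozen=True)
class MeanLimitReport:
    """Limits of the stationary mean population in the two noise regimes."""

    large_beta_limit: float
    small_beta: float
    eps_grid: tuple
    small_beta_means: tuple
    diverges_logarithmically: bool


def mean_limits(params: LogisticModelParams, small_beta: float = 0.05,
                eps_grid=(0.5, 0.1, 0.02), t_eval: float = 50.0,
                cmax: float = 1e6) -> MeanLimitReport:
    """Large- and small-beta behavior of the stationary mean.

    The large-beta limit is the carrying capacity ``gamma/epsilon`` exactly
    (undefined for epsilon = 0).  The small-beta behavior is probed by
    quadrature at a fixed small beta over a grid of decreasing epsilon with a
    fixed population cutoff; the report flags logarithmic divergence when the
    means increase monotonically as epsilon shrinks.  (The exact prefactor of
    the small-beta law is not asserted; only the qualitative divergence is.)
    """
    if params.epsilon == 0:
        raise UndefinedLimitError("large-beta mean limit is undefined for epsilon = 0")
    means = []
    for eps in eps_grid:
        p = LogisticModelParams(C0=params.C0, gamma=params.gamma, epsilon=eps,
                                noise=params.noise)
        means.append(logistic_mean(t_eval, p, mode="stationary_beta",
                                   beta_star=small_beta, cmax=cmax))
    increasing = all(m2 > m1 for m1, m2 in zip(means, means[1:]))
    return MeanLimitReport(
        large_beta_limit=params.gamma / params.epsilon,
        small_beta=small_beta,
        eps_grid=tuple(eps_grid),
        small_beta_means=tuple(means),
        diverges_logarithmically=increasing,
    )


# --------------------------------------------------------- growth-rate profile

@dataclass
class GrowthRateProfile:
    """Local growth rate values on a population grid at one time point."""

    c_grid: np.ndarray
    chi: np.ndarray
    t: float


def local_growth_rate_chi(c_grid, t, params: LogisticModelParams,
                          mode: str = "time_dependent",
                          beta_star: float | None = None) -> GrowthRateProfile:
    """Closed-form local growth rate ``chi(C, t) = (1/P) dP/dt`` (approximate form).

    chi ~ gamma e^{-2 gamma t} / (1 - e^{-2 gamma t}) * [-1 + 2 beta z^2]
          - 2 beta z (gamma/C0 - epsilon) e^{-gamma t},   z = 1/C - A(t).

    The expression drops the correlation-time corrections to d(beta)/dt, so it
    is exact only in the short-correlation-time regime; for an independent
    numerical evaluation use :func:`numeric_chi`.
    """
    c = np.asarray(c_grid, dtype=float)
    if np.any(c <= 0):
        raise InvalidInputError("population grid must be positive")
    t = float(_check_t(t, allow_zero=False))
    g = params.gamma
    denom = -np.expm1(-2.0 * g * t)  # 1 - e^{-2 gamma t}
    if denom == 0.0:
        raise InvalidInputError(f"t={t} too small: 1 - e^(-2 gamma t) underflows")
    beta = _resolve_beta(t, params, mode, beta_star)
    if not np.isfinite(beta):
        raise InvalidInputError(f"t={t} too small: beta is infinite (degenerate density)")
    A = A_of(t, params)
    z = 1.0 / c - A
    term1 = g * np.exp(-2.0 * g * t) / denom * (-1.0 + 2.0 * beta * z * z)
    term2 = -2.0 * beta * z * (g / params.C0 - params.epsilon) * np.exp(-g * t)
    return GrowthRateProfile(c_grid=c, chi=term1 + term2, t=t)


def numeric_chi(c_grid, t, params: LogisticModelParams, dt: float = 1e-5,
                mode: str = "time_dependent",
                beta_star: float | None = None) -> GrowthRateProfile:
    """Finite-difference oracle for the local growth rate.

    ``(1/P) dP/dt = d ln P / dt`` by central difference of the closed-form
    density; independent of the approximations in
    :func:`local_growth_rate_chi`.
    """
    c = np.asarray(c_grid, dtype=float)
    t = float(_check_t(t, allow_zero=False))
    if t - dt <= 0:
        raise InvalidInputError("t - dt must stay positive for the central difference")
    lo = np.log(logistic_pdf(c, t - dt, params, mode, beta_star))
    hi = np.log(logistic_pdf(c, t + dt, params, mode, beta_star))
    return GrowthRateProfile(c_grid=c, chi=(hi - lo) / (2.0 * dt), t=t)


def mean_growth_rate(t, params: LogisticModelParams, mode: str = "time_dependent",
                     beta_star: float | None = None, dt: float = 1e-4) -> float:
    """Growth rate of the mean population, ``(1/<C>) d<C>/dt``, by quadrature."""
    t = float(_check_t(t, allow_zero=False))
    if t - dt <= 0:
        raise InvalidInputError("t - dt must stay positive for the central difference")
    m_lo = logistic_mean(t - dt, params, mode, beta_star)
    m_hi = logistic_mean(t + dt, params, mode, beta_star)
    return (np.log(m_hi) - np.log(m_lo)) / (2.0 * dt)


# ------------------------------------------------------------- solution facades

@dataclass(frozen=True)
class LinearSolution:
    """Bundled evaluators for the linear model's closed-form solution."""

    params: LinearModelParams

    def gamma_sq(self, t):
        return gamma_sq(t, self.params.noise)

    def alpha(self, t):
        return alpha(t, self.params.noise)

    def pdf(self, c, t):
        return linear_pdf(c, t, self.params)

    def cdf(self, c, t):
        return linear_cdf(c, t, self.params)

    def moments(self, t):
        return linear_moments(t, self.params)

    def mean(self, t):
        return linear_moments(t, self.params)[0]

    def dispersion(self, t, approx: bool = False):
        if approx:
            return linear_dispersion_approx(t, self.params)
        return linear_moments(t, self.params)[1]


@dataclass(frozen=True)
class LogisticSolution:
    """Bundled evaluators for the logistic model's closed-form solution.

    ``mode`` selects how beta is obtained: ``"time_dependent"`` (from the noise
    parameters via the closed variance form) or ``"stationary_beta"`` (held
    fixed at ``beta_star``).
    """

    params: LogisticModelParams
    mode: str = "time_dependent"
    beta_star: float | None = None

    def __post_init__(self):
        if self.mode not in _MODES:
            raise InvalidInputError(f"mode must be one of {_MODES}")
        if self.mode == "stationary_beta" and (self.beta_star is None or self.beta_star <= 0):
            raise InvalidInputError("stationary_beta mode requires beta_star > 0")

    def A(self, t):
        return A_of(t, self.params)

    def z_var(self, t):
        return z_var(t, self.params)

    def beta(self, t):
        return _resolve_beta(t, self.params, self.mode, self.beta_star)

    def normalization(self, t):
        return normalization(t, self.params, self.beta(t))

    def pdf(self, c, t):
        return logistic_pdf(c, t, self.params, self.mode, self.beta_star)

    def cdf(self, c, t):
        return logistic_cdf(c, t, self.params, self.mode, self.beta_star)

    def mean(self, t, cmax: float | None = None):
        return logistic_mean(t, self.params, self.mode, self.beta_star, cmax)

    def chi(self, c_grid, t):
        return local_growth_rate_chi(c_grid, t, self.params, self.mode, self.beta_star)
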