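"""Ensemble simulators for noise-driven clonal growth.

Three models share the colored-noise growth rate ``g_c``:

* linear multiplicative growth      dC/dt = (gamma_const + g_c) C
* reduced logistic self-regulation  dC/dt = gamma C - (epsilon + g_c) C^2
* coupled growth-input system       dC/dt = G C,  dG/dt = gamma - (epsilon + g_c) C - G

Conditioned on a noise path the dynamics are ordinary differential equations,
so integration uses exact OU noise paths plus deterministic schemes: the linear
model is solved exactly through its exponential-of-integral form, the nonlinear
models with an adaptive Heun (predictor-corrector) stepper that halves the step
where the local error estimate exceeds tolerance.

The logistic model can blow up in finite time when ``epsilon + g_c`` stays
negative.  Two schemes are offered:

* ``"reciprocal"`` (default) integrates the transformed variable
  ``y = 1/C`` (whose dynamics ``dy/dt = -gamma y + epsilon + g_c`` are linear
  in ``y``), which passes smoothly through the blow-up; populations beyond the
  cap are flagged per time point and may later return below it.
* ``"population"`` integrates the population equation directly; replicates
  crossing the cap are flagged diverged and frozen there.

The reciprocal scheme is the default because freezing blown-up replicates
biases the observable (non-diverged) distribution away from the closed-form
solution, which conditions only on the state at the observation time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .colored_noise import NoiseParams, sample_ou, _check_times
from .errors import EmptyHistogramError, InvalidInputError, ParameterError

__all__ = [
    "LinearModelParams",
    "LogisticModelParams",
    "CoupledModelParams",
    "TrajectoryEnsemble",
    "simulate_linear",
    "simulate_logistic",
    "simulate_coupled",
    "ensemble_histogram",
    "default_dt",
]

_LINEAR_CAP = 1e300


@dataclass(frozen=True)
class LinearModelParams:
    """Multiplicative-growth model: total growth rate ``gamma_const + g_c``."""

    C0: float
    noise: NoiseParams
    gamma_const: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.C0) or self.C0 <= 0:
            raise ParameterError(f"initial population C0 must be > 0, got {self.C0}")


@dataclass(frozen=True)
class LogisticModelParams:
    """Reduced self-regulation model with constitutive input ``gamma`` and
    coherent self-regulation ``epsilon``; the stochastic part of the
    self-regulation is the noise path itself."""

    C0: float
    gamma: float
    epsilon: float
    noise: NoiseParams

    def __post_init__(self) -> None:
        if not np.isfinite(self.C0) or self.C0 <= 0:
            raise ParameterError(f"initial population C0 must be > 0, got {self.C0}")
        if not np.isfinite(self.gamma) or self.gamma <= 0:
            raise ParameterError(f"gamma must be > 0, got {self.gamma}")
        if not np.isfinite(self.epsilon) or self.epsilon < 0:
            raise ParameterError(f"epsilon must be >= 0, got {self.epsilon}")

    @property
    def carrying_capacity(self) -> float:
        """Deterministic fixed point ``gamma / epsilon``; undefined for epsilon=0."""
        if self.epsilon == 0:
            raise ParameterError("carrying capacity is undefined when epsilon = 0")
        return self.gamma / self.epsilon


@dataclass(frozen=True)
class CoupledModelParams:
    """Full growth-input system with explicit relaxing input ``G``."""

    C0: float
    G0: float
    gamma: float
    epsilon: float
    noise: NoiseParams

    def __post_init__(self) -> None:
        if not np.isfinite(self.C0) or self.C0 <= 0:
            raise ParameterError(f"initial population C0 must be > 0, got {self.C0}")


@dataclass
class TrajectoryEnsemble:
    """Replicate-by-time matrix of populations with divergence bookkeeping.

    ``diverged_at`` marks entries whose stored value is the overflow cap rather
    than a valid population; ``diverged`` flags replicates that crossed the cap
    at any point, with ``first_divergence_time`` the first crossing.
    """

    times: np.ndarray
    values: np.ndarray
    params: object
    seed: int
    cap: float | None = None
    diverged: np.ndarray | None = None
    first_divergence_time: np.ndarray | None = None
    diverged_at: np.ndarray | None = None
    g_input: np.ndarray | None = None  # G paths (coupled model only)
    final_noise: np.ndarray | None = None  # per-replicate g_c at the last time

    def __post_init__(self) -> None:
        self.times = _check_times(self.times)
        self.values = np.asarray(self.values, dtype=float)
        n_reps = self.values.shape[0]
        if self.diverged_at is None:
            self.diverged_at = np.zeros_like(self.values, dtype=bool)
        if self.diverged is None:
            self.diverged = self.diverged_at.any(axis=1)
        if self.first_divergence_time is None:
            self.first_divergence_time = np.full(n_reps, np.nan)

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    def time_index(self, t: float) -> int:
        idx = np.flatnonzero(np.isclose(self.times, t, rtol=0, atol=1e-9 + 1e-9 * abs(t)))
        if idx.size == 0:
            raise InvalidInputError(f"t={t} is not on the output time grid")
        return int(idx[0])

    def at(self, t: float) -> tuple[np.ndarray, int]:
        """Non-diverged population values at time ``t`` plus excluded count."""
        k = self.time_index(t)
        ok = ~self.diverged_at[:, k]
        return self.values[ok, k], int((~ok).sum())

    def moments(self, t: float) -> tuple[float, float, int]:
        """(mean, dispersion, n_excluded) at ``t``, warning if replicates were dropped."""
        vals, n_excluded = self.at(t)
        if n_excluded:
            warnings.warn(
                f"{n_excluded} diverged replicate(s) excluded from moments at t={t}",
                stacklevel=2,
            )
        return float(vals.mean()), float(vals.std(ddof=1)), n_excluded

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(self.values.T, columns=[f"rep{i}" for i in range(self.n_replicates)])
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)
        meta = {
            "seed": self.seed,
            "cap": self.cap,
            "model": type(self.params).__name__,
            "n_diverged": int(self.diverged.sum()),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def default_dt(noise: NoiseParams, gamma: float | None = None) -> float:
    """Default integration step: resolve the noise and the fastest drift scale."""
    drift_scale = min(1.0 / gamma, 1.0) if gamma else 1.0
    return min(noise.tau_c / 10.0, 0.01 * drift_scale)


def _refine(times: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly subdivide each interval of ``times`` to steps <= dt.

    Returns the fine grid and the indices of the requested times within it.
    A leading 0 is prepended when the requested grid does not start at 0, so
    trajectories are always integrated from the initial condition at t=0.
    """
    times = _check_times(times)
    if times[0] < 0:
        raise InvalidInputError("time grid must be non-negative")
    prepend = times[0] > 0
    knots = np.concatenate([[0.0], times]) if prepend else times
    fine = [np.array([knots[0]])]
    idx = [0]
    for t0, t1 in zip(knots[:-1], knots[1:]):
        m = max(1, int(np.ceil((t1 - t0) / dt - 1e-9)))
        fine.append(t0 + (t1 - t0) * np.arange(1, m + 1) / m)
        idx.append(idx[-1] + m)
    out_idx = np.asarray(idx[1:] if prepend else idx, dtype=int)
    return np.concatenate(fine), out_idx


def simulate_linear(
    params: LinearModelParams,
    times: np.ndarray,
    n_reps: int,
    seed: int,
    *,
    dt: float | None = None,
    stationary: bool = True,
    c0: np.ndarray | None = None,
    noise_g0: np.ndarray | None = None,
) -> TrajectoryEnsemble:
    """Exact sampling of the linear model: ``C(t) = C0 exp(gamma_const t + Gamma(t))``
    with ``Gamma`` the trapezoid-rule path integral of the noise on the fine grid.

    ``c0`` optionally supplies per-replicate initial populations (used by
    iterated-selection runs); it must have length ``n_reps``.
    """
    if dt is None:
        dt = default_dt(params.noise)
    fine, out_idx = _refine(times, dt)
    ens = sample_ou(params.noise, fine, n_reps, seed, stationary=stationary,
                    g0=noise_g0)
    gamma_paths = cumulative_trapezoid(ens.values, fine, axis=1, initial=0.0)
    c0_arr = np.full(n_reps, params.C0, dtype=float) if c0 is None else np.asarray(c0, dtype=float)
    if c0_arr.shape != (n_reps,):
        raise InvalidInputError("c0 must have shape (n_reps,)")
    log_c = np.log(c0_arr)[:, None] + params.gamma_const * fine[None, :] + gamma_paths
    with np.errstate(over="ignore"):
        values = np.exp(log_c[:, out_idx])
    diverged_at = ~np.isfinite(values) | (values > _LINEAR_CAP)
    values = np.where(diverged_at, _LINEAR_CAP, values)
    return TrajectoryEnsemble(
        times=np.asarray(times, dtype=float), values=values, params=params, seed=seed,
        cap=_LINEAR_CAP, diverged_at=diverged_at, final_noise=ens.values[:, -1].copy(),
    )


def _adaptive_heun(state, g_start, g_end, dt, rhs, tol, depth, max_depth):
    """One Heun step on all replicates, recursively halving failing columns.

    ``state`` has shape (n_vars, n_reps); noise arrays have shape (n_reps,).
    Returns the new state and a per-replicate failure flag (step underflow).
    """
    k1 = rhs(state, g_start)
    with np.errstate(over="ignore", invalid="ignore"):
        pred = state + dt * k1
        k2 = rhs(pred, g_end)
        new = state + 0.5 * dt * (k1 + k2)
        err = 0.5 * dt * np.abs(k2 - k1)
        scale = np.abs(state) + np.abs(new) + 1.0
        bad = np.any(err > tol * scale, axis=0) | ~np.all(np.isfinite(new), axis=0)
    if not np.any(bad):
        return new, np.zeros(state.shape[1], dtype=bool)
    if depth >= max_depth:
        return new, bad
    g_mid = 0.5 * (g_start[bad] + g_end[bad])
    half1, f1 = _adaptive_heun(state[:, bad], g_start[bad], g_mid, dt / 2, rhs, tol,
                               depth + 1, max_depth)
    half2, f2 = _adaptive_heun(half1, g_mid, g_end[bad], dt / 2, rhs, tol,
                               depth + 1, max_depth)
    new[:, bad] = half2
    fail = np.zeros(state.shape[1], dtype=bool)
    fail[bad] = f1 | f2
    return new, fail


def _resolve_cap(params, cap: float | None) -> float:
    if cap is not None:
        if cap <= params.C0:
            raise InvalidInputError(f"cap must exceed C0={params.C0}")
        return float(cap)
    eps = getattr(params, "epsilon", 0.0)
    return 1e6 * (params.gamma / eps) if eps > 0 else 1e6


def simulate_logistic(
    params: LogisticModelParams,
    times: np.ndarray,
    n_reps: int,
    seed: int,
    *,
    cap: float | None = None,
    dt: float | None = None,
    scheme: str = "reciprocal",
    tol: float = 1e-6,
    stationary: bool = True,
    c0: np.ndarray | None = None,
    noise_g0: np.ndarray | None = None,
) -> TrajectoryEnsemble:
    """Integrate the reduced logistic model along exact OU noise paths.

    See the module docstring for the two schemes and the divergence policy.
    """
    if scheme not in ("reciprocal", "population"):
        raise InvalidInputError(f"unknown scheme {scheme!r}")
    if dt is None:
        dt = default_dt(params.noise, params.gamma)
    cap = _resolve_cap(params, cap)
    fine, out_idx = _refine(times, dt)
    noise = sample_ou(params.noise, fine, n_reps, seed, stationary=stationary,
                      g0=noise_g0)
    g = noise.values
    gamma, eps = params.gamma, params.epsilon
    c0_arr = np.full(n_reps, params.C0, dtype=float) if c0 is None else np.asarray(c0, dtype=float)

    times_out = np.asarray(times, dtype=float)
    values = np.empty((n_reps, out_idx.size))
    diverged_at = np.zeros((n_reps, out_idx.size), dtype=bool)
    first_div = np.full(n_reps, np.nan)
    out_pos = {int(k): j for j, k in enumerate(out_idx)}

    if scheme == "reciprocal":
        def rhs(y, gg):
            return -gamma * y + eps + gg

        y = (1.0 / c0_arr)[None, :]
        y_floor = 1.0 / cap
        for k in range(fine.size):
            if k > 0:
                h = fine[k] - fine[k - 1]
                y, fail = _adaptive_heun(y, g[:, k - 1], g[:, k], h, rhs, tol, 0, 12)
                over = (y[0] <= y_floor) | fail
                newly = over & np.isnan(first_div)
                first_div[newly] = fine[k]
            if k in out_pos:
                j = out_pos[k]
                over_now = y[0] <= y_floor
                diverged_at[:, j] = over_now
                with np.errstate(divide="ignore", over="ignore"):
                    values[:, j] = np.where(over_now, cap, 1.0 / y[0])
    else:
        def rhs(c, gg):
            return gamma * c - (eps + gg) * c * c

        c = c0_arr.copy()[None, :]
        frozen = np.zeros(n_reps, dtype=bool)
        for k in range(fine.size):
            if k > 0:
                h = fine[k] - fine[k - 1]
                live = ~frozen
                if np.any(live):
                    new, fail = _adaptive_heun(c[:, live], g[live, k - 1], g[live, k],
                                               h, rhs, tol, 0, 12)
                    blown = fail | (new[0] > cap) | (new[0] <= 0) | ~np.isfinite(new[0])
                    new[0] = np.where(blown, cap, new[0])
                    c[:, live] = new
                    idx_live = np.flatnonzero(live)
                    frozen[idx_live[blown]] = True
                    first_div[idx_live[blown]] = np.where(
                        np.isnan(first_div[idx_live[blown]]), fine[k],
                        first_div[idx_live[blown]])
            if k in out_pos:
                j = out_pos[k]
                values[:, j] = c[0]
                diverged_at[:, j] = frozen

    return TrajectoryEnsemble(
        times=times_out, values=values, params=params, seed=seed, cap=cap,
        diverged=~np.isnan(first_div), first_divergence_time=first_div,
        diverged_at=diverged_at, final_noise=g[:, -1].copy(),
    )


def simulate_coupled(
    params: CoupledModelParams,
    times: np.ndarray,
    n_reps: int,
    seed: int,
    *,
    cap: float | None = None,
    dt: float | None = None,
    tol: float = 1e-6,
    stationary: bool = True,
) -> TrajectoryEnsemble:
    """Joint Heun integration of the population and its relaxing growth input.

    Returns an ensemble whose ``values`` are the population paths and whose
    ``g_input`` attribute carries the matching growth-input paths.  Replicates
    crossing the cap are flagged and frozen (same policy as the population
    scheme of :func:`simulate_logistic`).
    """
    if dt is None:
        dt = default_dt(params.noise, params.gamma if params.gamma > 0 else None)
    cap = _resolve_cap(params, cap)
    fine, out_idx = _refine(times, dt)
    noise = sample_ou(params.noise, fine, n_reps, seed, stationary=stationary)
    g = noise.values
    gamma, eps = params.gamma, params.epsilon

    def rhs(state, gg):
        c, gr = state
        return np.stack([gr * c, gamma - (eps + gg) * c - gr])

    state = np.stack([np.full(n_reps, params.C0, dtype=float), np.full(n_reps, params.G0, dtype=float)])
    frozen = np.zeros(n_reps, dtype=bool)
    first_div = np.full(n_reps, np.nan)
    values = np.empty((n_reps, out_idx.size))
    g_paths = np.empty((n_reps, out_idx.size))
    diverged_at = np.zeros((n_reps, out_idx.size), dtype=bool)
    out_pos = {int(k): j for j, k in enumerate(out_idx)}
    for k in range(fine.size):
        if k > 0:
            h = fine[k] - fine[k - 1]
            live = ~frozen
            if np.any(live):
                new, fail = _adaptive_heun(state[:, live], g[live, k - 1], g[live, k],
                                           h, rhs, tol, 0, 12)
                blown = fail | (new[0] > cap) | (new[0] <= 0) | ~np.all(np.isfinite(new), axis=0)
                new[0] = np.where(blown, cap, new[0])
                state[:, live] = new
                idx_live = np.flatnonzero(live)
                frozen[idx_live[blown]] = True
                first_div[idx_live[blown]] = fine[k]
        if k in out_pos:
            j = out_pos[k]
            values[:, j] = state[0]
            g_paths[:, j] = state[1]
            diverged_at[:, j] = frozen

    return TrajectoryEnsemble(
        times=np.asarray(times, dtype=float), values=values, params=params, seed=seed,
        cap=cap, diverged=~np.isnan(first_div), first_divergence_time=first_div,
        diverged_at=diverged_at, g_input=g_paths,
    )


def ensemble_histogram(
    ensemble: TrajectoryEnsemble, t: float, bins: int | np.ndarray = 50
) -> pd.DataFrame:
    """Empirical density of the non-diverged replicates at time ``t``.

    Returns a table (bin_left, bin_right, density) normalized so the density
    integrates to 1 over the binned support; the number of excluded diverged
    replicates is stored in ``DataFrame.attrs["n_excluded"]``.
    """
    vals, n_excluded = ensemble.at(t)
    if vals.size == 0:
        raise EmptyHistogramError(f"all replicates diverged at t={t}")
    density, edges = np.histogram(vals, bins=bins, density=True)
    out = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "density": density}
    )
    out.attrs["n_excluded"] = n_excluded
    out.attrs["n_used"] = int(vals.size)
    out.attrs["t"] = t
    return out
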