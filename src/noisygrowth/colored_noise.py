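"""Exponentially correlated Gaussian growth-rate noise.

The driving process ``g_c`` is the stationary Ornstein--Uhlenbeck process with

    <g_c(t) g_c(t')> = D * exp(-|t - t'| / tau_c),

i.e. mean zero, stationary variance ``D`` and autocorrelation time ``tau_c``.
The white-noise regime is the ``tau_c -> 0`` limit taken at fixed ``D * tau_c``
and is obtained here simply by choosing a small ``tau_c`` (there is no separate
generator).  Sampling uses the exact discrete-time update

    g(t + dt) = g(t) * exp(-dt/tau_c) + sqrt(D * (1 - exp(-2 dt/tau_c))) * xi,

which reproduces the target autocovariance identically at any step size.

Also provided: ensemble autocovariance estimation, recovery of ``(D, tau_c)``
from an estimated autocovariance curve, and the two-state (sign) Markov
decomposition used to quantify intermittency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import FitError, InvalidInputError, ParameterError

__all__ = [
    "NoiseParams",
    "NoiseEnsemble",
    "MarkovDecomposition",
    "sample_ou",
    "estimate_autocorrelation",
    "fit_noise_params",
    "markov_decompose",
]


@dataclass(frozen=True)
class NoiseParams:
    """Magnitude ``D`` (stationary variance, 1/time^2) and correlation time ``tau_c``."""

    D: float
    tau_c: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.D) or self.D < 0:
            raise ParameterError(f"noise magnitude D must be finite and >= 0, got {self.D}")
        if not np.isfinite(self.tau_c) or self.tau_c <= 0:
            raise ParameterError(f"correlation time tau_c must be finite and > 0, got {self.tau_c}")

    def to_dict(self) -> dict:
        return {"D": self.D, "tau_c": self.tau_c}


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise InvalidInputError("time grid must be a non-empty 1-D array")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise InvalidInputError("time grid must be strictly increasing")
    return times


def _uniform_dt(times: np.ndarray) -> float:
    """Return the common step of a uniform grid, or raise."""
    diffs = np.diff(times)
    if diffs.size == 0:
        raise InvalidInputError("need at least two time points")
    dt = diffs[0]
    if not np.allclose(diffs, dt, rtol=1e-8, atol=1e-12):
        raise InvalidInputError("operation requires a uniform time grid")
    return float(dt)


@dataclass
class NoiseEnsemble:
    """Replicate-by-time matrix of growth-rate samples.

    Each row is one independent realization of the stationary process; the
    ensemble is reproducible from ``(params, seed)`` and the time grid.
    """

    times: np.ndarray
    values: np.ndarray  # shape (n_replicates, n_times)
    params: NoiseParams
    seed: int
    stationary_start: bool = True

    def __post_init__(self) -> None:
        self.times = _check_times(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != self.times.size:
            raise InvalidInputError(
                f"values shape {self.values.shape} does not match {self.times.size} time points"
            )

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """Write ``time`` plus one column per replicate; JSON sidecar holds params."""
        path = Path(path)
        df = pd.DataFrame(
            self.values.T, columns=[f"rep{i}" for i in range(self.n_replicates)]
        )
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "params": self.params.to_dict(),
                    "seed": self.seed,
                    "stationary_start": self.stationary_start,
                    "n_replicates": self.n_replicates,
                },
                indent=2,
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "NoiseEnsemble":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            times=df["time"].to_numpy(),
            values=df.drop(columns="time").to_numpy().T,
            params=NoiseParams(**meta["params"]),
            seed=meta["seed"],
            stationary_start=meta.get("stationary_start", True),
        )


@dataclass(frozen=True)
class MarkovDecomposition:
    """Sign-state (0 = non-positive, 1 = positive) transition frequencies at interval ``dt``."""

    p00: float
    p01: float
    p10: float
    p11: float
    pi0: float
    pi1: float
    dt: float


def sample_noise_increments(params: NoiseParams, times: np.ndarray, n_reps: int, seed: int):
    """Per-replicate standard-normal innovations, one stream per replicate.

    Streams are spawned from a single root seed so that enlarging ``n_reps``
    never alters earlier replicates.  Returns ``(g0, xi)`` with ``g0`` the
    standard-normal draw for the initial value and ``xi`` of shape
    ``(n_reps, n_times - 1)``.
    """
    n_steps = times.size - 1
    g0 = np.empty(n_reps)
    xi = np.empty((n_reps, n_steps))
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_reps)):
        rng = np.random.default_rng(child)
        g0[i] = rng.standard_normal()
        if n_steps:
            xi[i] = rng.standard_normal(n_steps)
    return g0, xi


def sample_ou(
    params: NoiseParams,
    times: np.ndarray,
    n_reps: int,
    seed: int,
    *,
    stationary: bool = True,
    g0: np.ndarray | None = None,
) -> NoiseEnsemble:
    """Draw ``n_reps`` independent realizations of the colored noise on ``times``.

    Parameters
    ----------
    stationary:
        If True (default) the initial value is drawn from the stationary law
        N(0, D); otherwise the process starts cold at 0 and relaxes into
        stationarity over a few ``tau_c``.
    g0:
        Optional per-replicate initial noise values (shape ``(n_reps,)``),
        overriding ``stationary``; used to continue a process across
        simulation segments without losing its memory.
    """
    times = _check_times(times)
    if n_reps < 1:
        raise InvalidInputError(f"n_reps must be >= 1, got {n_reps}")
    D, tau = params.D, params.tau_c
    g0_std, xi = sample_noise_increments(params, times, n_reps, seed)
    if g0 is not None:
        g0 = np.asarray(g0, dtype=float)
        if g0.shape != (n_reps,):
            raise InvalidInputError("g0 must have shape (n_reps,)")
    else:
        g0 = np.sqrt(D) * g0_std if stationary else np.zeros(n_reps)

    dts = np.diff(times)
    values = np.empty((n_reps, times.size))
    values[:, 0] = g0
    if dts.size:
        rho = np.exp(-dts / tau)
        sig = np.sqrt(D * (1.0 - rho**2))
        if np.allclose(dts, dts[0], rtol=1e-8, atol=1e-12):
            # uniform grid: AR(1) recursion as a linear filter across all replicates
            x = sig[0] * xi
            zi = (rho[0] * g0)[:, None]
            values[:, 1:], _ = lfilter([1.0], [1.0, -rho[0]], x, axis=-1, zi=zi)
        else:
            g = g0.copy()
            for k in range(dts.size):
                g = g * rho[k] + sig[k] * xi[:, k]
                values[:, k + 1] = g
    return NoiseEnsemble(times=times, values=values, params=params, seed=seed,
                         stationary_start=stationary)


def estimate_autocorrelation(ensemble: NoiseEnsemble, max_lag: float) -> pd.DataFrame:
    """Unbiased ensemble-average autocovariance estimate on the sampling grid.

    Returns a table with columns ``lag``, ``estimate``, ``stderr``.  For lag
    ``k * dt`` the estimator averages ``x(t) x(t + k dt)`` over time and
    replicates; the standard error is computed across replicate means.
    """
    span = ensemble.times[-1] - ensemble.times[0]
    if max_lag >= span:
        raise InvalidInputError(f"max_lag {max_lag} must be smaller than the grid span {span}")
    if max_lag < 0:
        raise InvalidInputError("max_lag must be non-negative")
    dt = _uniform_dt(ensemble.times)
    k_max = int(np.floor(max_lag / dt + 1e-9))
    x = ensemble.values
    n_reps = x.shape[0]
    rows = []
    for k in range(k_max + 1):
        prod = x[:, : x.shape[1] - k] * x[:, k:] if k else x * x
        per_rep = prod.mean(axis=1)
        est = per_rep.mean()
        stderr = per_rep.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else np.nan
        rows.append((k * dt, est, stderr))
    return pd.DataFrame(rows, columns=["lag", "estimate", "stderr"])


def fit_noise_params(autocorr_table: pd.DataFrame) -> tuple[float, float]:
    """Recover ``(D, tau_c)`` from an autocovariance table.

    ``D`` is read off the lag-0 estimate; ``tau_c`` comes from an ordinary
    least-squares fit of ``log(estimate)`` against positive lags.  Lags whose
    estimate has decayed below ``D * e^-3`` are excluded: out there the
    estimator is sampling-noise dominated and would bias the log-linear fit.
    """
    table = autocorr_table
    lag = np.asarray(table["lag"], dtype=float)
    est = np.asarray(table["estimate"], dtype=float)
    at_zero = est[np.isclose(lag, 0.0)]
    if at_zero.size == 0:
        raise FitError("autocorrelation table must contain a lag-0 row")
    D_hat = float(at_zero[0])
    if D_hat <= 0:
        raise FitError(f"non-positive variance estimate at lag 0: {D_hat}")
    mask = (lag > 0) & (est > 0) & (est >= D_hat * np.exp(-3.0))
    if mask.sum() < 3:
        bad = ((lag > 0) & (est <= 0)).sum()
        raise FitError(
            "need >= 3 positive-lag points with positive estimates above the "
            f"noise floor (have {int(mask.sum())}; {int(bad)} non-positive estimates)"
        )
    slope, _ = np.polyfit(lag[mask], np.log(est[mask]), 1)
    if slope >= 0:
        raise FitError(f"autocovariance does not decay (fitted slope {slope:.3g} >= 0)")
    return D_hat, float(-1.0 / slope)


def markov_decompose(ensemble: NoiseEnsemble) -> MarkovDecomposition:
    """Two-state Markov summary of the sign process of the noise.

    Values > 0 map to state 1 (growth), values <= 0 to state 0 (decay; the
    measure-zero tie at exactly 0 is deliberately assigned to state 0 for
    determinism).  Transition frequencies are pooled over replicates and
    row-normalized.
    """
    if ensemble.n_times < 2:
        raise InvalidInputError("markov decomposition needs at least two time points")
    dt = _uniform_dt(ensemble.times)
    s = (ensemble.values > 0).astype(np.int8)
    a, b = s[:, :-1].ravel(), s[:, 1:].ravel()
    counts = np.zeros((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            counts[i, j] = np.count_nonzero((a == i) & (b == j))
    row = counts.sum(axis=1)
    p = np.divide(counts, row[:, None], out=np.full((2, 2), np.nan), where=row[:, None] > 0)
    occ = s.mean()
    return MarkovDecomposition(
        p00=float(p[0, 0]), p01=float(p[0, 1]), p10=float(p[1, 0]), p11=float(p[1, 1]),
        pi0=float(1.0 - occ), pi1=float(occ), dt=dt,
    )
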