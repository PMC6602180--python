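"""Cross-validated prediction and Monte-Carlo parameter-uncertainty bands."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .fitting import CycleData, FitProblem, FitResult, fit, pooled_rmse
from .models import ModelConstants, ModelSpec, PDParameters, simulate_model
from .pk import InfusionSchedule, PKParameters


def steady_state_params(core: PDParameters, consts: ModelConstants) -> PDParameters:
    """Fill the initial-state parameters with their homeostatic values
    (B0 = B, marrow compartments at B_bm) for out-of-sample simulation."""
    bbm = core.b_bm(consts)
    return replace(core, b0=core.b, xpr0=bbm, xtr0=bbm)


@dataclass
class PredictionResult:
    fit: FitResult
    times: np.ndarray
    predicted: np.ndarray
    observed: np.ndarray
    rmse: float


def cross_validate_last_cycle(cycles: Sequence[CycleData], model: ModelSpec,
                              consts: ModelConstants, pk: PKParameters,
                              **fit_kwargs) -> PredictionResult:
    """Fit on all but the last cycle, then predict the held-out last cycle.

    The held-out cycle contributes only its dosing schedule and observation
    *times* to the prediction step; its WBC values are used solely to score
    the prediction.  The predicted cycle starts from the homeostatic state
    implied by the fitted baseline (its own initial state cannot be
    estimated without touching the held-out data).
    """
    if len(cycles) < 2:
        raise ValueError("cross-validation needs at least two cycles")
    train, test = list(cycles[:-1]), cycles[-1]
    problem = FitProblem(model=model, cycles=train, consts=consts, pk=pk, **fit_kwargs)
    result = fit(problem)
    core = problem.unpack(result.estimates)[0]
    params = steady_state_params(core, consts)
    grid = np.unique(np.concatenate([[0.0], test.times]))
    traj = simulate_model(model, params, consts, pk, test.schedule, grid)
    lookup = dict(zip(traj.times, traj.wbc))
    pred = np.array([lookup[t] for t in test.times])
    return PredictionResult(fit=result, times=test.times, predicted=pred,
                            observed=test.wbc, rmse=pooled_rmse(pred, test.wbc))


@dataclass
class UncertaintyBand:
    times: np.ndarray
    quantiles: dict[float, np.ndarray]
    n_samples: int
    n_resampled: int


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    sym = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(sym)
    if np.min(w) >= 0:
        return sym
    return (v * np.maximum(w, 0.0)) @ v.T


def monte_carlo_band(problem: FitProblem, result: FitResult, grid: np.ndarray,
                     n: int = 1000, seed: int = 0,
                     levels: tuple[float, ...] = (2.5, 50.0, 97.5),
                     schedule: Optional[InfusionSchedule] = None,
                     cycle_index: int = 0) -> UncertaintyBand:
    """Propagate the estimation covariance through the model by simulation.

    ``n`` parameter vectors are drawn from the multivariate normal at
    (estimate, covariance); draws violating the positivity bounds are
    resampled (up to 100 attempts each) rather than clipped, so that the
    band's quantiles are not distorted at the box edges.  Pointwise WBC
    quantiles at the requested ``levels`` (percent) are returned.
    """
    if result.covariance is None:
        raise ValueError("fit carries no covariance; cannot propagate uncertainty")
    cov = _nearest_psd(np.asarray(result.covariance))
    mean = np.asarray(result.estimates, dtype=float)
    lo, hi = problem.bounds_arrays()
    rng = np.random.default_rng(seed)
    sched = schedule if schedule is not None else problem.cycles[cycle_index].schedule
    grid = np.asarray(grid, dtype=float)

    wbc = np.empty((n, grid.size))
    n_resampled = 0
    chol_ok = np.any(cov)
    for i in range(n):
        theta = mean
        if chol_ok:
            for _ in range(100):
                theta = rng.multivariate_normal(mean, cov, method="cholesky")
                if np.all(theta >= lo) and np.all(theta <= hi):
                    break
                n_resampled += 1
            else:
                theta = mean
        params = problem.unpack(theta)[cycle_index]
        traj = simulate_model(problem.model, params, problem.consts, problem.pk,
                              sched, grid, rtol=problem.rtol, atol=problem.atol)
        wbc[i] = traj.wbc
    quantiles = {lev: np.percentile(wbc, lev, axis=0) for lev in sorted(levels)}
    return UncertaintyBand(times=grid, quantiles=quantiles, n_samples=n,
                           n_resampled=n_resampled)
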