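"""Empirical Bayesian (MAP) estimation and individual bilirubin forecasting.

Given a trained population model rho = (Theta_pop, Omega, beta, sigma) and a
new neonate's measurements w_i, the individual random effects are estimated
as the mode of the -2 log posterior

    eta_hat = argmin  sum_j [ (w_ij - f_ij)^2/(sigma f_ij)^2
                              + log(2 pi (sigma f_ij)^2) ]
              + eta' Omega^{-1} eta + log det(2 pi Omega),

started at eta = 0 (the prior mode, which is also the exact solution when no
measurements are available).  The individualized parameters then drive a
forward prediction of the bilirubin trajectory from the last used measurement
(the anchor) out to the requested horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._inference import make_subject_data, neg2_joint_batch, newton_map
from .io import NeonateRecord
from .model import (
    InvalidInputError,
    StructuralParameters,
    individualize,
    solve_trajectory,
)
from .population import PopulationModel

__all__ = [
    "IndividualEstimate",
    "PredictionResult",
    "map_estimate",
    "predict_horizon",
    "predict_at",
]

#: Prediction horizons beyond this (the stress-test bound) trigger a warning.
DEFAULT_MAX_HORIZON_H = 60.0


@dataclass(frozen=True)
class IndividualEstimate:
    """MAP solution for one neonate."""

    record_id: str
    theta_hat: StructuralParameters
    eta_hat: np.ndarray
    objective: float  # -2 log p(Theta_i | w_i; rho) at the mode
    converged: bool


@dataclass(frozen=True)
class PredictionResult:
    """Forward prediction from the anchor time over a horizon."""

    record_id: str
    anchor_time: float  # PNA (h) of the last measurement used, 0 if none
    horizon: float
    time_grid: np.ndarray
    predictions: np.ndarray  # umol/l on time_grid
    point_prediction: float  # Bpred at anchor_time + horizon


def map_estimate(
    record: NeonateRecord,
    model: PopulationModel,
    tol: float = 1e-8,
    n_starts: int = 1,
    jitter_seed: int = 0,
) -> IndividualEstimate:
    """MAP-estimate the individual parameters of one neonate.

    ``n_starts > 1`` adds jittered restarts around eta = 0 (the posterior is
    near-quadratic at routine data densities, so one start is the default).
    """
    if record.measurements and record.times[0] <= 0:
        raise InvalidInputError("measurements must be at postnatal age > 0")
    d = len(model.random_effect_names)
    base = model.base_theta(record.covariates)
    omega_inv, logdet = model.omega_inverse()
    subj = make_subject_data(
        base, model.random_effect_names, record.times, record.values
    )
    fun = lambda eta: neg2_joint_batch(
        eta, subj, model.sigma_prop, omega_inv, logdet
    )

    if len(record.measurements) == 0 or d == 0:
        eta_hat = np.zeros(d)
        value = float(fun(eta_hat[None, :])[0])
        ok = True
    else:
        starts = [np.zeros(d)]
        if n_starts > 1:
            rng = np.random.default_rng(jitter_seed)
            sd = np.sqrt(np.maximum(np.diag(model.omega), 1e-12))
            starts += [rng.normal(0.0, sd) for _ in range(n_starts - 1)]
        best = None
        for s in starts:
            eta, value, _, ok = newton_map(fun, d, s, tol=tol)
            if best is None or value < best[1]:
                best = (eta, value, ok)
        eta_hat, value, ok = best

    theta_hat = individualize(
        StructuralParameters.from_array(base), eta_hat, model.random_effect_names
    )
    return IndividualEstimate(
        record_id=record.record_id,
        theta_hat=theta_hat,
        eta_hat=eta_hat,
        objective=float(value),
        converged=bool(ok),
    )


def predict_horizon(
    estimate: IndividualEstimate,
    record: NeonateRecord,
    horizon: float,
    grid_step: float = 0.5,
    max_horizon: float = DEFAULT_MAX_HORIZON_H,
) -> PredictionResult:
    """Predict the individual trajectory over ``horizon`` hours past the anchor.

    The anchor is the PNA of the last measurement in ``record`` (0 h when the
    record has none: a purely prior, covariate-typical prediction).  The
    trajectory is solved from birth, so the returned curve is consistent with
    the model's initial condition.
    """
    if horizon <= 0:
        raise InvalidInputError("horizon must be > 0")
    if horizon > max_horizon:
        warnings.warn(
            f"horizon {horizon} h exceeds the validated maximum {max_horizon} h",
            stacklevel=2,
        )
    if not estimate.converged:
        raise InvalidInputError("cannot predict from a non-converged estimate")
    anchor = float(record.times[-1]) if record.measurements else 0.0
    n = int(np.ceil(horizon / grid_step))
    grid = np.minimum(anchor + grid_step * np.arange(n + 1), anchor + horizon)
    grid = np.unique(np.append(grid, anchor + horizon))
    solve_times = grid if grid[0] > 0 else grid[1:]
    values = solve_trajectory(estimate.theta_hat, solve_times)
    if grid[0] == 0:
        values = np.concatenate([[estimate.theta_hat.b0], values])
    return PredictionResult(
        record_id=estimate.record_id,
        anchor_time=anchor,
        horizon=float(horizon),
        time_grid=grid,
        predictions=values,
        point_prediction=float(values[-1]),
    )


def predict_at(
    estimate: IndividualEstimate, times: np.ndarray | list[float]
) -> np.ndarray:
    """Model prediction at arbitrary postnatal ages for a fitted individual."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    order = np.argsort(times)
    sorted_times = times[order]
    if np.any(sorted_times < 0):
        raise InvalidInputError("prediction times must be >= 0")
    uniq, inv = np.unique(sorted_times, return_inverse=True)
    solve_times = uniq if uniq[0] > 0 else uniq[1:]
    vals = solve_trajectory(estimate.theta_hat, solve_times) if solve_times.size else np.empty(0)
    if uniq[0] == 0:
        vals = np.concatenate([[estimate.theta_hat.b0], vals])
    out = np.empty_like(times)
    out[order] = vals[inv]
    return out
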