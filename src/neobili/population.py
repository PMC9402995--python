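"""Population (nonlinear mixed-effects) fitting of the bilirubin model.

The hierarchical model: subject i has parameters

    Theta_i = individualize(apply_covariates(Theta_pop, beta, c_i), eta_i),
    eta_i ~ N(0, Omega)   (log-scale random effects on a configurable subset),

and observations w_ij = f(t_ij; Theta_i) * (1 + sigma * eps_ij) with
eps ~ N(0,1), i.e. a proportional residual-error model with SD sigma*f.

The marginal likelihood is approximated by the Laplace method: for each
subject the -2 log joint is minimized over eta (inner MAP problem) and the
log-determinant curvature correction added.  When a subject carries no random
effects the Laplace approximation is the exact -2 log likelihood.  Population
parameters are estimated by quasi-Newton descent on an unconstrained
reparameterization (log for positive scalars, logit for the elimination
deficit M_e, log-Cholesky for Omega).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from ._inference import (
    laplace_term,
    make_subject_data,
    neg2_joint_batch,
    newton_map,
)
from .io import NeonateRecord
from .model import (
    PARAM_NAMES,
    CovariateEffects,
    InvalidInputError,
    StructuralParameters,
    apply_covariates,
)

__all__ = [
    "PopulationModel",
    "FitConfig",
    "FitResult",
    "CovariateDecision",
    "marginal_objective",
    "fit_population",
    "evaluate_covariate",
]

#: Parameters carrying random effects by default; the maturation shape
#: parameters (A_p, T_p, M_e, T_e) are population-level only, which keeps the
#: per-subject problem identifiable at 2-4 measurements per neonate.
DEFAULT_RANDOM_EFFECTS = ("b0", "p_ss", "k_ss")

BETA_NAMES = ("beta_bw", "beta_ga", "beta_cs")

#: Structural parameter whose typical value each covariate effect scales.
BETA_TARGET = {"beta_bw": "p_ss", "beta_ga": "k_ss", "beta_cs": "k_ss"}

#: chi-square(df=1) critical value at alpha = 0.05 for forward inclusion.
DELTA_OFV_CRITICAL = 3.84


@dataclass(frozen=True)
class PopulationModel:
    """Trained prior rho = (Theta_pop, Omega, beta) plus residual error sigma."""

    theta_pop: StructuralParameters
    omega: np.ndarray
    beta: CovariateEffects
    sigma_prop: float
    random_effect_names: tuple[str, ...] = DEFAULT_RANDOM_EFFECTS

    def __post_init__(self) -> None:
        omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        if omega.size == 0:
            omega = omega.reshape(0, 0)
        object.__setattr__(self, "omega", omega)
        object.__setattr__(
            self, "random_effect_names", tuple(self.random_effect_names)
        )
        d = len(self.random_effect_names)
        if omega.shape != (d, d):
            raise InvalidInputError(
                f"omega shape {omega.shape} does not match "
                f"{d} random-effect names"
            )
        if d:
            if not np.allclose(omega, omega.T, atol=1e-12):
                raise InvalidInputError("omega must be symmetric")
            if np.min(np.linalg.eigvalsh(omega)) < -1e-12:
                raise InvalidInputError("omega must be positive semidefinite")
        unknown = set(self.random_effect_names) - set(PARAM_NAMES)
        if unknown:
            raise InvalidInputError(f"unknown random-effect names: {sorted(unknown)}")
        if not 0.0 < self.sigma_prop < 1.0:
            raise InvalidInputError("sigma_prop must be in (0, 1)")

    def base_theta(self, covariates) -> np.ndarray:
        """Covariate-adjusted typical parameter vector for one subject."""
        return apply_covariates(self.theta_pop, self.beta, covariates).as_array()

    def omega_inverse(self) -> tuple[np.ndarray, float]:
        """(Omega^-1, log det(2 pi Omega)); raises on singular Omega."""
        d = self.omega.shape[0]
        if d == 0:
            return np.empty((0, 0)), 0.0
        sign, logdet = np.linalg.slogdet(self.omega)
        if sign <= 0 or not np.isfinite(logdet):
            raise np.linalg.LinAlgError(
                "omega is singular; regularize or drop a random effect"
            )
        return np.linalg.inv(self.omega), d * math.log(2.0 * math.pi) + logdet


@dataclass
class FitConfig:
    """Options controlling :func:`fit_population`."""

    fix: frozenset[str] = frozenset()  # fixed effects held at their init value
    estimate_betas: tuple[str, ...] = ()  # covariate effects estimated
    full_omega: bool = False  # full covariance via log-Cholesky (else diagonal)
    max_outer_iter: int = 500
    outer_tol: float = 1e-6
    inner_tol: float = 1e-8

    def __post_init__(self) -> None:
        self.fix = frozenset(self.fix)
        unknown = self.fix - set(PARAM_NAMES)
        if unknown:
            raise InvalidInputError(f"unknown fixed-effect names in fix: {sorted(unknown)}")
        unknown = set(self.estimate_betas) - set(BETA_NAMES)
        if unknown:
            raise InvalidInputError(f"unknown covariate effects: {sorted(unknown)}")


@dataclass
class FitResult:
    model: PopulationModel
    ofv: float
    converged: bool
    n_subjects: int
    n_observations: int
    eta_modes: dict[str, np.ndarray] = field(default_factory=dict)
    n_free_parameters: int = 0
    message: str = ""


# ---------------------------------------------------------------------------
# Marginal objective (Laplace)
# ---------------------------------------------------------------------------

def _subject_objective(
    model: PopulationModel,
    record: NeonateRecord,
    omega_inv: np.ndarray,
    logdet: float,
    eta0: np.ndarray | None,
    inner_tol: float,
):
    subj = make_subject_data(
        model.base_theta(record.covariates),
        model.random_effect_names,
        record.times,
        record.values,
    )
    fun = lambda eta: neg2_joint_batch(
        eta, subj, model.sigma_prop, omega_inv, logdet
    )
    d = len(model.random_effect_names)
    eta_hat, value, hess, ok = newton_map(fun, d, eta0, tol=inner_tol)
    return eta_hat, laplace_term(value, hess), ok


def marginal_objective(
    model: PopulationModel,
    cohort: list[NeonateRecord],
    warm_start: dict[str, np.ndarray] | None = None,
    inner_tol: float = 1e-8,
) -> float:
    """-2 log (Laplace-approximate) marginal likelihood of the cohort.

    ``warm_start`` maps record_id to a starting eta for the inner MAP problem
    and is updated in place with the modes found (keyed by record id, so the
    result is invariant to subject order).
    """
    if any(len(r.measurements) == 0 for r in cohort):
        raise InvalidInputError("every record must have at least one measurement")
    omega_inv, logdet = model.omega_inverse()
    total = 0.0
    for rec in cohort:
        eta0 = warm_start.get(rec.record_id) if warm_start is not None else None
        eta_hat, contrib, ok = _subject_objective(
            model, rec, omega_inv, logdet, eta0, inner_tol
        )
        if not ok and not np.isfinite(contrib):
            return float("inf")
        if warm_start is not None:
            warm_start[rec.record_id] = eta_hat
        total += contrib
    return float(total)


# ---------------------------------------------------------------------------
# Parameter packing for the outer optimization
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


class _Packer:
    """Bijection between a PopulationModel and an unconstrained vector."""

    def __init__(self, init: PopulationModel, config: FitConfig):
        self.config = config
        self.re_names = init.random_effect_names
        self.free_theta = [n for n in PARAM_NAMES if n not in config.fix]
        self.free_betas = tuple(config.estimate_betas)
        self.d = len(self.re_names)
        self.init = init

    @property
    def n_free(self) -> int:
        n_omega = self.d * (self.d + 1) // 2 if self.config.full_omega else self.d
        return len(self.free_theta) + n_omega + 1 + len(self.free_betas)

    def pack(self, model: PopulationModel) -> np.ndarray:
        x = []
        for name in self.free_theta:
            v = getattr(model.theta_pop, name)
            x.append(_logit(v) if name == "m_e" else math.log(v))
        if self.config.full_omega and self.d:
            chol = np.linalg.cholesky(model.omega)
            for i in range(self.d):
                for j in range(i + 1):
                    x.append(math.log(chol[i, i]) if i == j else chol[i, j])
        else:
            x.extend(0.5 * math.log(v) for v in np.diag(model.omega))
        x.append(math.log(model.sigma_prop))
        x.extend(getattr(model.beta, b) for b in self.free_betas)
        return np.array(x, dtype=float)

    def unpack(self, x: np.ndarray) -> PopulationModel:
        x = np.asarray(x, dtype=float)
        k = 0
        updates = {}
        for name in self.free_theta:
            updates[name] = _expit(x[k]) if name == "m_e" else math.exp(x[k])
            k += 1
        theta = self.init.theta_pop.replace(**updates)
        if self.config.full_omega and self.d:
            chol = np.zeros((self.d, self.d))
            for i in range(self.d):
                for j in range(i + 1):
                    chol[i, j] = math.exp(x[k]) if i == j else x[k]
                    k += 1
            omega = chol @ chol.T
        else:
            sds = np.exp(x[k : k + self.d])
            omega = np.diag(sds**2)
            k += self.d
        sigma = math.exp(x[k])
        k += 1
        beta_updates = {}
        for b in self.free_betas:
            beta_updates[b] = float(x[k])
            k += 1
        beta = replace(self.init.beta, **beta_updates)
        sigma = min(sigma, 0.999)
        return PopulationModel(
            theta_pop=theta,
            omega=omega,
            beta=beta,
            sigma_prop=sigma,
            random_effect_names=self.re_names,
        )


# ---------------------------------------------------------------------------
# Population fit and covariate evaluation
# ---------------------------------------------------------------------------

def fit_population(
    cohort: list[NeonateRecord],
    init: PopulationModel,
    config: FitConfig | None = None,
) -> FitResult:
    """Estimate (Theta_pop, Omega, beta, sigma) by Laplace marginal likelihood.

    The reported OFV never exceeds the OFV of ``init`` (the best iterate is
    kept).  Raises when the cohort has fewer observations than free
    parameters.
    """
    if not cohort:
        raise InvalidInputError("cohort is empty")
    config = config or FitConfig()
    packer = _Packer(init, config)
    n_obs = sum(len(r.measurements) for r in cohort)
    if n_obs < packer.n_free:
        raise InvalidInputError(
            f"{n_obs} observations cannot support {packer.n_free} free parameters"
        )

    warm: dict[str, np.ndarray] = {}
    best = {"x": packer.pack(init), "ofv": float("inf")}

    def objective(x: np.ndarray) -> float:
        try:
            model = packer.unpack(x)
            ofv = marginal_objective(
                model, cohort, warm_start=warm, inner_tol=config.inner_tol
            )
        except (np.linalg.LinAlgError, InvalidInputError, OverflowError):
            return 1e12
        if not np.isfinite(ofv):
            return 1e12
        if ofv < best["ofv"]:
            best["ofv"] = ofv
            best["x"] = x.copy()
        return ofv

    x0 = packer.pack(init)
    ofv0 = objective(x0)
    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        options={
            "maxiter": config.max_outer_iter,
            "ftol": 1e-10,
            "gtol": config.outer_tol,
            "eps": 1e-5,
        },
    )
    x_best, ofv_best = best["x"], min(best["ofv"], ofv0)
    model = packer.unpack(x_best)
    # final pass to collect per-subject modes at the returned estimate
    modes: dict[str, np.ndarray] = {}
    ofv_final = marginal_objective(
        model, cohort, warm_start=modes, inner_tol=config.inner_tol
    )
    ofv_best = min(ofv_best, ofv_final)
    return FitResult(
        model=model,
        ofv=float(ofv_best),
        converged=bool(res.success),
        n_subjects=len(cohort),
        n_observations=n_obs,
        eta_modes=modes,
        n_free_parameters=packer.n_free,
        message=str(res.message),
    )


@dataclass
class CovariateDecision:
    candidate: str
    delta_ofv: float
    significant: bool
    p_value: float
    delta_random_effect_variance: float | None
    fit: FitResult


def evaluate_covariate(
    cohort: list[NeonateRecord],
    base_fit: FitResult,
    candidate: str,
    config: FitConfig | None = None,
) -> CovariateDecision:
    """Forward-inclusion test of one covariate effect.

    Refits with ``candidate`` (e.g. ``"beta_bw"``) free, and reports
    Delta-OFV = OFV_base - OFV_candidate, significance against
    chi-square(1) at alpha = 0.05 (Delta-OFV > 3.84), and the change in the
    omega diagonal of the parameter the covariate acts on (None when that
    parameter carries no random effect).
    """
    if candidate not in BETA_NAMES:
        raise InvalidInputError(f"unknown covariate effect {candidate!r}")
    if not base_fit.converged:
        raise InvalidInputError("base fit did not converge")
    base_cfg = config or FitConfig()
    cand_cfg = replace(
        base_cfg,
        estimate_betas=tuple(dict.fromkeys((*base_cfg.estimate_betas, candidate))),
    )
    cand_fit = fit_population(cohort, base_fit.model, cand_cfg)
    delta = base_fit.ofv - cand_fit.ofv
    p_value = float(stats.chi2.sf(max(delta, 0.0), df=1))
    target = BETA_TARGET[candidate]
    if target in base_fit.model.random_effect_names:
        k_base = base_fit.model.random_effect_names.index(target)
        k_cand = cand_fit.model.random_effect_names.index(target)
        dvar = float(
            base_fit.model.omega[k_base, k_base] - cand_fit.model.omega[k_cand, k_cand]
        )
    else:
        dvar = None
    return CovariateDecision(
        candidate=candidate,
        delta_ofv=float(delta),
        significant=bool(delta > DELTA_OFV_CRITICAL),
        p_value=p_value,
        delta_random_effect_variance=dvar,
        fit=cand_fit,
    )
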