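"""Virtual neonatal cohorts for development and validation of the algorithm.

No clinical bilirubin dataset ships with the package, so every other module
is exercised on synthetic cohorts that emulate the covariate structure,
sampling schedules and measurement noise of a real perinatal-center dataset:

* gestational age from a left-skewed truncated distribution with median
  38+2 weeks (268 d), quartiles 36+2 / 39+6, range 24+0 to 42+2;
* birth weight conditional on gestational age (linear growth relation,
  ~180 g per week, residual SD 400 g), median ~3,085 g;
* cesarean-section fraction 620/1101;
* 1-10 TSB measurements per neonate averaging ~2.8, first sample drawn in a
  clinically plausible window after birth, later samples spaced >= 8 h;
* proportional measurement noise with CV ~10% (clinical TSB variability is
  of the order 5-15%).

Generated observations come from a known "true" population model, and the
per-neonate true parameters are returned separately so that estimation
methods can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import Measurement, NeonateRecord
from .model import (
    PARAM_NAMES,
    Covariates,
    CovariateEffects,
    InvalidInputError,
    StructuralParameters,
    apply_covariates,
    individualize,
    trajectory_batch,
)
from .population import DEFAULT_RANDOM_EFFECTS, PopulationModel

__all__ = ["CohortDesign", "default_truth", "generate_cohort", "cohort_summary"]

# Truncated skew-normal for gestational age (days), calibrated so the
# truncated quantiles match the validation-cohort targets
# Q1/median/Q3 = 254/268/279 d on support [168, 296].
_GA_SKEW_A = -3.27480153
_GA_SKEW_LOC = 288.5682707
_GA_SKEW_SCALE = 29.64330323
_GA_LO, _GA_HI = 168.0, 296.0

_BW_SLOPE_G_PER_DAY = 180.0 / 7.0  # fetal growth ~180 g/week near term
_BW_RESID_SD_G = 400.0
_BW_LO, _BW_HI = 400.0, 6000.0


@dataclass
class CohortDesign:
    """Design of a synthetic cohort (defaults emulate the validation center)."""

    n_neonates: int = 200
    p_cesarean: float = 620.0 / 1101.0
    ga_median_target: float = 268.0  # 38+2 weeks, days
    ga_window: tuple[float, float] = (_GA_LO, _GA_HI)  # truncation bounds, days
    bw_median_target: float = 3085.0  # g
    id_prefix: str = "N"
    mean_measurements: float = 2.8
    max_measurements: int = 10
    measurements_exact: int | None = None  # fixed count, overrides the mean
    first_sample_window: tuple[float, float] = (10.0, 60.0)
    spacing_minimum: float = 8.0
    mean_extra_spacing: float = 16.0  # exponential gap beyond the minimum, h
    sigma_prop: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neonates < 0:
            raise InvalidInputError("n_neonates must be >= 0")
        if not 0.0 <= self.p_cesarean <= 1.0:
            raise InvalidInputError("p_cesarean must be in [0, 1]")
        lo, hi = self.first_sample_window
        if not 0 < lo < hi:
            raise InvalidInputError("invalid first_sample_window")
        if self.spacing_minimum <= 0 or self.mean_extra_spacing < 0:
            raise InvalidInputError("invalid spacing configuration")
        if self.measurements_exact is None:
            # a truncated geometric on {1..kmax} cannot exceed the uniform mean
            if not 1.0 <= self.mean_measurements < (self.max_measurements + 1) / 2:
                raise InvalidInputError("mean_measurements outside feasible range")
        elif self.measurements_exact < 1:
            raise InvalidInputError("measurements_exact must be >= 1")
        if self.sigma_prop < 0:
            raise InvalidInputError("sigma_prop must be >= 0")
        glo, ghi = self.ga_window
        if not _GA_LO <= glo < ghi <= _GA_HI:
            raise InvalidInputError(
                f"ga_window must be within [{_GA_LO}, {_GA_HI}] days"
            )


def default_truth() -> PopulationModel:
    """The true population model behind the default synthetic cohorts.

    Typical values give a term neonate a TSB peak of ~150-170 umol/l around
    day 2-3 declining toward a mature steady state P_ss/K_ss ~ 54 umol/l;
    production is 2.5-fold elevated at birth (half-life 36 h) and elimination
    90% immature at birth (maturation half-life 60 h).  Covariate effects are
    oriented by physiology: production per plasma volume rises as birth
    weight falls (shorter fetal red-cell lifespan in preterm infants), and
    elimination capacity matures steeply with gestational age, so a 28-week
    infant peaks near 290 umol/l while a 42-week infant peaks near 115.
    Log-normal between-subject variability on B0, P_ss and K_ss
    (SD 0.25/0.20/0.25) spreads individual peaks further, populating both
    sides of the 250 umol/l phototherapy threshold.
    """
    theta = StructuralParameters(
        b0=45.0, p_ss=1.9, a_p=1.5, t_p=36.0, k_ss=0.035, m_e=0.90, t_e=60.0
    )
    omega = np.diag(np.array([0.25, 0.20, 0.25]) ** 2)
    beta = CovariateEffects(
        beta_bw=-0.4, beta_ga=3.0, beta_cs=-0.1, ref_bw=2500.0, ref_ga=265.0
    )
    return PopulationModel(
        theta_pop=theta,
        omega=omega,
        beta=beta,
        sigma_prop=0.10,
        random_effect_names=DEFAULT_RANDOM_EFFECTS,
    )


def _truncated_geometric_p(mean: float, kmax: int) -> float:
    """Success probability of a geometric on {1..kmax} with the given mean."""
    ks = np.arange(1, kmax + 1)

    def mean_at(p: float) -> float:
        w = p * (1.0 - p) ** (ks - 1)
        return float((ks * w).sum() / w.sum())

    if mean >= kmax:  # degenerate: all mass at kmax
        return 1e-12
    return optimize.brentq(lambda p: mean_at(p) - mean, 1e-9, 1 - 1e-9)


def _sample_covariates(design: CohortDesign, rng: np.random.Generator):
    d = stats.skewnorm(_GA_SKEW_A, loc=_GA_SKEW_LOC, scale=_GA_SKEW_SCALE)
    flo, fhi = d.cdf(design.ga_window[0]), d.cdf(design.ga_window[1])
    ga = d.ppf(rng.uniform(flo, fhi, design.n_neonates))
    bw_mean = design.bw_median_target + _BW_SLOPE_G_PER_DAY * (
        ga - design.ga_median_target
    )
    bw = np.clip(
        bw_mean + rng.normal(0.0, _BW_RESID_SD_G, design.n_neonates),
        _BW_LO,
        _BW_HI,
    )
    cs = rng.uniform(size=design.n_neonates) < design.p_cesarean
    return ga, bw, cs


def generate_cohort(
    design: CohortDesign,
    truth: PopulationModel | None = None,
) -> tuple[list[NeonateRecord], pd.DataFrame]:
    """Generate a synthetic cohort and its hidden per-neonate truth.

    Returns ``(records, truth_table)``: the observed records (noisy
    measurements) and a DataFrame, indexed by record id, of the true
    individual structural parameters and random effects used to generate
    them (for recovery tests; never consumed by the estimation code).
    """
    truth = truth or default_truth()
    rng = np.random.default_rng(design.seed)
    if design.n_neonates == 0:
        return [], pd.DataFrame()
    ga, bw, cs = _sample_covariates(design, rng)
    if design.measurements_exact is not None:
        n_meas = np.full(design.n_neonates, design.measurements_exact)
    else:
        p_geo = _truncated_geometric_p(
            design.mean_measurements, design.max_measurements
        )
        ks = np.arange(1, design.max_measurements + 1)
        w = p_geo * (1.0 - p_geo) ** (ks - 1)
        n_meas = rng.choice(ks, size=design.n_neonates, p=w / w.sum())

    d = len(truth.random_effect_names)
    etas = (
        rng.multivariate_normal(np.zeros(d), truth.omega, size=design.n_neonates)
        if d
        else np.zeros((design.n_neonates, 0))
    )

    records: list[NeonateRecord] = []
    truth_rows = []
    width = len(str(max(design.n_neonates - 1, 1)))
    for i in range(design.n_neonates):
        rid = f"{design.id_prefix}{i:0{width}d}"
        cov = Covariates(
            gestational_age=float(ga[i]),
            birth_weight=float(bw[i]),
            delivery_mode="cesarean" if cs[i] else "vaginal",
        )
        typical = apply_covariates(truth.theta_pop, truth.beta, cov)
        params = individualize(typical, etas[i], truth.random_effect_names)
        t = design.first_sample_window[0] + rng.uniform() * (
            design.first_sample_window[1] - design.first_sample_window[0]
        )
        times = [t]
        for _ in range(int(n_meas[i]) - 1):
            t += design.spacing_minimum + rng.exponential(design.mean_extra_spacing)
            times.append(t)
        times = np.array(times)
        true_vals = trajectory_batch(params.as_array()[None, :], times)[0]
        noise = rng.standard_normal(times.size)
        obs = np.maximum(true_vals * (1.0 + design.sigma_prop * noise), 1.0)
        records.append(
            NeonateRecord(
                rid, cov, tuple(Measurement(float(a), float(b)) for a, b in zip(times, obs))
            )
        )
        row = {"record_id": rid}
        row.update({name: getattr(params, name) for name in PARAM_NAMES})
        row.update(
            {f"eta_{n}": float(e) for n, e in zip(truth.random_effect_names, etas[i])}
        )
        truth_rows.append(row)
    truth_table = pd.DataFrame(truth_rows).set_index("record_id")
    return records, truth_table


# ---------------------------------------------------------------------------
# Descriptive summary
# ---------------------------------------------------------------------------

def _five_numbers(x: np.ndarray) -> dict[str, float]:
    # linear-interpolation (type-7) quantiles, the numpy default
    return {
        "median": float(np.median(x)),
        "q1": float(np.quantile(x, 0.25)),
        "q3": float(np.quantile(x, 0.75)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }


def _weeks_days(days: float) -> str:
    w, r = divmod(int(round(days)), 7)
    return f"{w}+{r}"


def cohort_summary(cohort: list[NeonateRecord]) -> dict:
    """Cohort characteristics table: Median [Q1, Q3] (Min, Max) plus counts."""
    if not cohort:
        raise InvalidInputError("cohort is empty")
    ga = np.array([r.covariates.gestational_age for r in cohort])
    bw = np.array([r.covariates.birth_weight for r in cohort])
    last = np.array([r.times[-1] for r in cohort if r.measurements])
    n_meas = sum(len(r.measurements) for r in cohort)
    n_cs = sum(r.covariates.delivery_mode == "cesarean" for r in cohort)
    return {
        "n_neonates": len(cohort),
        "n_measurements": n_meas,
        "mean_measurements_per_neonate": n_meas / len(cohort),
        "n_cesarean": n_cs,
        "n_vaginal": len(cohort) - n_cs,
        "gestational_age_days": _five_numbers(ga),
        "birth_weight_g": _five_numbers(bw),
        "last_measurement_pna_h": _five_numbers(last) if last.size else None,
    }


def summary_text(summary: dict) -> str:
    """Render a cohort summary in Median [Q1, Q3] (Min, Max) layout."""
    ga = summary["gestational_age_days"]
    bw = summary["birth_weight_g"]
    lines = [
        f"{summary['n_neonates']} neonates with {summary['n_measurements']} "
        f"bilirubin values, average "
        f"{summary['mean_measurements_per_neonate']:.1f} values per neonate",
        "Gestational age (week+day): "
        f"{_weeks_days(ga['median'])} [{_weeks_days(ga['q1'])}, "
        f"{_weeks_days(ga['q3'])}] ({_weeks_days(ga['min'])}, {_weeks_days(ga['max'])})",
        "Weight at birth (g): "
        f"{bw['median']:,.0f} [{bw['q1']:,.0f}, {bw['q3']:,.0f}] "
        f"({bw['min']:,.0f}, {bw['max']:,.0f})",
        f"Delivery mode: {summary['n_cesarean']} C.S. {summary['n_vaginal']} vaginal",
    ]
    if summary["last_measurement_pna_h"]:
        lm = summary["last_measurement_pna_h"]
        lines.append(
            "Postnatal hour of last measurement: "
            f"{lm['median']:.1f} [{lm['q1']:.1f}, {lm['q3']:.1f}] "
            f"({lm['min']:.1f}, {lm['max']:.1f})"
        )
    return "\n".join(lines)
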