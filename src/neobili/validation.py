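"""Clinical validation of the prediction algorithm.

Implements the validation scenarios, dataset-construction rules, prediction
difference metrics, the Bland-Altman acceptance range, and the clinically
anchored sensitivity/specificity classification against the 250 umol/l
phototherapy threshold.

Scenarios
---------
S1   : 1 input measurement, predict up to 24 h past it (stress test: 30 h)
S2a  : 2 input measurements, predict up to 48 h past the second (stress: 60 h)
S2b  : >=2 input measurements, predict up to 48 h past the last (stress: 60 h)

Input rules (postnatal age, hours): first input in [8, 72]; every later input
in [24, 96]; successive inputs spaced >= 8 h apart.  Records that fail the
rules are filtered out, not errors.

Classification: a neonate is hyperbilirubinemic iff the observed value
exceeds 250 umol/l (strict).  Misclassified predictions whose difference
Bpred - Bobs falls inside the Bland-Altman 90% acceptance range
[MW - 1.6449 SD, MW + 1.6449 SD] are "accepted" true positives/negatives;
otherwise they are false negatives/positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ebe import map_estimate, predict_at
from .io import NeonateRecord
from .model import UMOL_PER_MGDL, InvalidInputError
from .population import PopulationModel

__all__ = [
    "THRESHOLD_UMOL_L",
    "Z_90",
    "ScenarioSpec",
    "ScenarioCase",
    "ClassificationOutcome",
    "ValidationReport",
    "prediction_difference",
    "relative_prediction_difference",
    "acceptance_range",
    "classify",
    "sensitivity_specificity",
    "build_scenario_cases",
    "run_validation",
]

logger = logging.getLogger("neobili")

#: Clinical hyperbilirubinemia threshold (phototherapy limit), umol/l.
THRESHOLD_UMOL_L = 250.0

#: 95th percentile of the standard normal, as used in the 90% limits of
#: agreement of the acceptance range.
Z_90 = 1.6449

_SCENARIOS = {
    ("S1", False): ("S1", 1, 24.0),
    ("S1", True): ("S1_stress", 1, 30.0),
    ("S2a", False): ("S2a", 2, 48.0),
    ("S2a", True): ("S2a_stress", 2, 60.0),
    ("S2b", False): ("S2b", -1, 48.0),  # -1: two or more
    ("S2b", True): ("S2b_stress", -1, 60.0),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One validation scenario: input-measurement count and horizon."""

    scenario_id: str
    n_input_measurements: int  # 1, 2, or -1 for "two or more"
    horizon_h: float

    @classmethod
    def from_name(cls, name: str, stress: bool = False) -> "ScenarioSpec":
        base = name.replace("_stress", "")
        stress = stress or name.endswith("_stress")
        try:
            sid, n, h = _SCENARIOS[(base, stress)]
        except KeyError:
            raise InvalidInputError(f"unknown scenario {name!r}") from None
        return cls(sid, n, h)


@dataclass(frozen=True)
class ScenarioCase:
    """One constructed validation case: inputs plus the held-out target."""

    record_id: str
    record: NeonateRecord  # inputs only (measurements after target removed)
    target_time: float  # PNA (h) of the measurement to predict
    target_value: float  # Bobs, umol/l


@dataclass(frozen=True)
class ClassificationOutcome:
    record_id: str
    b_pred: float
    b_obs: float
    difference: float  # Bpred - Bobs
    category: str  # TP, accepted_TP, TN, accepted_TN, FP, FN


@dataclass
class ValidationReport:
    scenario_id: str
    n_cases: int
    median_rpd_pct: float
    median_pd_umol_l: float
    median_pd_mg_dl: float
    mw_diff: float
    sd_diff: float
    acceptance_range: tuple[float, float]
    sensitivity_pct: float | None
    specificity_pct: float | None
    counts: dict[str, int] = field(default_factory=dict)
    outcomes: list[ClassificationOutcome] = field(default_factory=list)

    def case_table(self) -> pd.DataFrame:
        """Observation-vs-prediction table, one row per validation case."""
        return pd.DataFrame(
            [
                {
                    "record_id": o.record_id,
                    "bpred_umol_l": o.b_pred,
                    "bobs_umol_l": o.b_obs,
                    "pd_umol_l": prediction_difference(o.b_pred, o.b_obs),
                    "rpd_pct": relative_prediction_difference(o.b_pred, o.b_obs),
                    "category": o.category,
                }
                for o in self.outcomes
            ]
        )

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "n_cases": self.n_cases,
            "median_rpd_pct": self.median_rpd_pct,
            "median_pd_umol_l": self.median_pd_umol_l,
            "median_pd_mg_dl": self.median_pd_mg_dl,
            "mw_diff": self.mw_diff,
            "sd_diff": self.sd_diff,
            "acceptance_range": list(self.acceptance_range),
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "counts": dict(self.counts),
        }


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def prediction_difference(b_pred: float, b_obs: float) -> float:
    """Absolute prediction difference |Bpred - Bobs| in umol/l."""
    if b_obs <= 0:
        raise InvalidInputError("Bobs must be > 0")
    return abs(b_pred - b_obs)


def relative_prediction_difference(b_pred: float, b_obs: float) -> float:
    """Relative (absolute) prediction difference |Bpred - Bobs| / Bobs * 100."""
    if b_obs <= 0:
        raise InvalidInputError("Bobs must be > 0")
    return abs(b_pred - b_obs) / b_obs * 100.0


def acceptance_range(differences) -> tuple[float, float]:
    """Bland-Altman 90% limits of agreement on Bpred - Bobs differences.

    [MW - 1.6449 SD, MW + 1.6449 SD] with the sample (n-1) standard deviation.
    """
    diffs = np.asarray(list(differences), dtype=float)
    if diffs.size < 2:
        raise InvalidInputError("need at least 2 differences")
    mw = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return (mw - Z_90 * sd, mw + Z_90 * sd)


def classify(
    b_pred: float,
    b_obs: float,
    threshold: float = THRESHOLD_UMOL_L,
    rng: tuple[float, float] = (0.0, 0.0),
) -> str:
    """Classify one prediction into the six clinical categories.

    Observed > threshold defines hyperbilirubinemia (positive class).  A
    discordant prediction is rescued ("accepted_TP"/"accepted_TN") when the
    difference Bpred - Bobs lies inside the acceptance range, and is FN/FP
    when it falls outside.
    """
    lower, upper = rng
    diff = b_pred - b_obs
    in_range = lower <= diff <= upper
    if b_obs > threshold:
        if b_pred > threshold:
            return "TP"
        return "accepted_TP" if in_range else "FN"
    if b_pred <= threshold:
        return "TN"
    return "accepted_TN" if in_range else "FP"


def sensitivity_specificity(
    outcomes: list[ClassificationOutcome],
) -> tuple[float | None, float | None]:
    """(sensitivity %, specificity %); None when the class is empty.

    sensitivity = (TP + accepted_TP) / (TP + accepted_TP + FN)
    specificity = (TN + accepted_TN) / (TN + accepted_TN + FP)
    """
    counts: dict[str, int] = {}
    for o in outcomes:
        counts[o.category] = counts.get(o.category, 0) + 1
    pos = counts.get("TP", 0) + counts.get("accepted_TP", 0)
    neg = counts.get("TN", 0) + counts.get("accepted_TN", 0)
    fn = counts.get("FN", 0)
    fp = counts.get("FP", 0)
    sens = 100.0 * pos / (pos + fn) if pos + fn > 0 else None
    spec = 100.0 * neg / (neg + fp) if neg + fp > 0 else None
    return sens, spec


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------

FIRST_INPUT_WINDOW = (8.0, 72.0)
LATER_INPUT_WINDOW = (24.0, 96.0)
MIN_SPACING_H = 8.0


def _input_rules_ok(times: np.ndarray) -> bool:
    if not FIRST_INPUT_WINDOW[0] <= times[0] <= FIRST_INPUT_WINDOW[1]:
        return False
    for t in times[1:]:
        if not LATER_INPUT_WINDOW[0] <= t <= LATER_INPUT_WINDOW[1]:
            return False
    return bool(np.all(np.diff(times) >= MIN_SPACING_H))


def build_scenario_cases(
    cohort: list[NeonateRecord], spec: ScenarioSpec
) -> list[ScenarioCase]:
    """Construct validation cases for one scenario; non-conforming records
    are silently dropped (with a logged count), mirroring clinical dataset
    construction where ineligible neonates are deleted.
    """
    cases: list[ScenarioCase] = []
    n_dropped = 0
    for rec in cohort:
        ms = rec.measurements
        if len(ms) < 2:  # patients with exactly one measurement are deleted
            n_dropped += 1
            continue
        if spec.n_input_measurements == 1:
            inputs = ms[:1]
            target = ms[1]
            if target.pna_h - inputs[-1].pna_h > spec.horizon_h:
                n_dropped += 1
                continue
        else:
            if len(ms) < 3:
                n_dropped += 1
                continue
            second = ms[1]
            target_idx = None
            for k in range(len(ms) - 1, 1, -1):  # step back from the last
                if ms[k].pna_h - second.pna_h <= spec.horizon_h:
                    target_idx = k
                    break
            if target_idx is None:
                n_dropped += 1
                continue
            target = ms[target_idx]
            if spec.n_input_measurements == 2:
                inputs = ms[:2]  # intermediates between 2nd and target deleted
            else:
                inputs = ms[:target_idx]  # two or more: intermediates kept
        times = np.array([m.pna_h for m in inputs])
        if not _input_rules_ok(times):
            n_dropped += 1
            continue
        cases.append(
            ScenarioCase(
                record_id=rec.record_id,
                record=NeonateRecord(rec.record_id, rec.covariates, tuple(inputs)),
                target_time=float(target.pna_h),
                target_value=float(target.tsb),
            )
        )
    if n_dropped:
        logger.info(
            "%s: %d records dropped by scenario construction/input rules",
            spec.scenario_id,
            n_dropped,
        )
    return cases


# ---------------------------------------------------------------------------
# Scenario execution
# ---------------------------------------------------------------------------

def run_validation(
    cohort: list[NeonateRecord],
    model: PopulationModel,
    spec: ScenarioSpec,
    threshold: float = THRESHOLD_UMOL_L,
) -> ValidationReport:
    """Run one validation scenario end to end.

    Each case is MAP-estimated on its input measurements only and the target
    measurement predicted; the acceptance range is computed from this
    scenario's own prediction differences before classification.
    """
    cases = build_scenario_cases(cohort, spec)
    if not cases:
        raise InvalidInputError(
            f"no eligible cases for scenario {spec.scenario_id}"
        )
    cases = sorted(cases, key=lambda c: c.record_id)
    preds = np.empty(len(cases))
    for i, case in enumerate(cases):
        est = map_estimate(case.record, model)
        preds[i] = predict_at(est, [case.target_time])[0]
    obs = np.array([c.target_value for c in cases])
    diffs = preds - obs
    if len(cases) >= 2:
        rng = acceptance_range(diffs)
    else:
        rng = (float(diffs[0]), float(diffs[0]))
    outcomes = [
        ClassificationOutcome(
            record_id=c.record_id,
            b_pred=float(p),
            b_obs=float(o),
            difference=float(p - o),
            category=classify(float(p), float(o), threshold, rng),
        )
        for c, p, o in zip(cases, preds, obs)
    ]
    sens, spec_pct = sensitivity_specificity(outcomes)
    counts: dict[str, int] = {}
    for o in outcomes:
        counts[o.category] = counts.get(o.category, 0) + 1
    pd_vals = np.abs(diffs)
    med_pd = float(np.median(pd_vals))
    return ValidationReport(
        scenario_id=spec.scenario_id,
        n_cases=len(cases),
        median_rpd_pct=float(np.median(pd_vals / obs * 100.0)),
        median_pd_umol_l=med_pd,
        median_pd_mg_dl=med_pd / UMOL_PER_MGDL,
        mw_diff=float(np.mean(diffs)),
        sd_diff=float(np.std(diffs, ddof=1)) if len(cases) >= 2 else 0.0,
        acceptance_range=rng,
        sensitivity_pct=sens,
        specificity_pct=spec_pct,
        counts=counts,
        outcomes=outcomes,
    )
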