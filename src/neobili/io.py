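"""Data containers, readers/writers and run configuration.

Cohort files are plain CSV, one row per TSB measurement:

    neonate_id, ga_days, birth_weight_g, delivery_mode, pna_h, tsb_umol_l

(or ``tsb_mg_dl`` when reading/writing in mg/dl; the canonical internal unit
is umol/l, converted at 17.1 umol/l per mg/dl).  Population models are stored
as flat JSON parameter files with units spelled out in the keys.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .model import (
    UMOL_PER_MGDL,
    Covariates,
    CovariateEffects,
    InvalidInputError,
    StructuralParameters,
)

__all__ = [
    "Measurement",
    "NeonateRecord",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "save_model",
    "load_model",
]

logger = logging.getLogger("neobili")

COHORT_COLUMNS = (
    "neonate_id",
    "ga_days",
    "birth_weight_g",
    "delivery_mode",
    "pna_h",
)


class Measurement(NamedTuple):
    pna_h: float
    tsb: float  # umol/l


@dataclass(frozen=True)
class NeonateRecord:
    """One neonate: covariates plus time-ordered TSB measurements."""

    record_id: str
    covariates: Covariates
    measurements: tuple[Measurement, ...] = ()

    def __post_init__(self) -> None:
        ms = tuple(Measurement(float(t), float(w)) for t, w in self.measurements)
        object.__setattr__(self, "measurements", ms)
        times = np.array([m.pna_h for m in ms])
        if times.size:
            if times[0] < 0:
                raise InvalidInputError("measurement PNA must be >= 0")
            if np.any(np.diff(times) <= 0):
                raise InvalidInputError(
                    f"record {self.record_id}: measurements must be strictly "
                    "increasing in PNA"
                )
            if any(m.tsb <= 0 for m in ms):
                raise InvalidInputError(f"record {self.record_id}: TSB must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.array([m.pna_h for m in self.measurements])

    @property
    def values(self) -> np.ndarray:
        return np.array([m.tsb for m in self.measurements])


@dataclass
class RunConfig:
    """Tool-level configuration shared by the CLI subcommands."""

    unit: str = "umol_l"  # or "mg_dl"
    solver_rtol: float = 1e-8
    solver_atol: float = 1e-10
    inner_tol: float = 1e-8
    outer_tol: float = 1e-6
    max_outer_iter: int = 500
    threshold_umol_l: float = 250.0
    max_horizon_h: float = 60.0
    prediction_grid_h: float = 0.5
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        for name in ("solver_rtol", "solver_atol", "inner_tol", "outer_tol",
                     "prediction_grid_h"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if self.unit not in ("umol_l", "mg_dl"):
            raise InvalidInputError("unit must be 'umol_l' or 'mg_dl'")


# ---------------------------------------------------------------------------
# Cohort CSV
# ---------------------------------------------------------------------------

def _tsb_column(unit: str) -> str:
    return "tsb_umol_l" if unit == "umol_l" else "tsb_mg_dl"


def read_cohort(path, unit: str = "umol_l") -> list[NeonateRecord]:
    """Read a cohort CSV into NeonateRecords, grouped and time-ordered.

    mg/dl values are converted to umol/l (x 17.1).  A duplicated
    (neonate_id, pna_h) pair is a hard error; a record with a missing
    covariate is skipped with a logged warning; malformed measurement rows
    are dropped with a logged warning.
    """
    col = _tsb_column(unit)
    df = pd.read_csv(path, dtype={"neonate_id": str}, float_precision="round_trip")
    required = set(COHORT_COLUMNS) | {col}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"cohort file missing columns: {sorted(missing)}")

    numeric = ["ga_days", "birth_weight_g", "pna_h", col]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    bad = df[["pna_h", col]].isna().any(axis=1)
    if bad.any():
        logger.warning("dropping %d malformed measurement rows", int(bad.sum()))
        df = df[~bad]

    dup = df.duplicated(subset=["neonate_id", "pna_h"])
    if dup.any():
        pairs = df.loc[dup, ["neonate_id", "pna_h"]].to_records(index=False)
        raise InvalidInputError(f"duplicate (neonate_id, pna_h) pairs: {list(pairs)[:5]}")

    records: list[NeonateRecord] = []
    for rid, grp in df.groupby("neonate_id", sort=True):
        grp = grp.sort_values("pna_h")
        row = grp.iloc[0]
        if (
            pd.isna(row["ga_days"])
            or pd.isna(row["birth_weight_g"])
            or pd.isna(row["delivery_mode"])
        ):
            logger.warning("record %s skipped: missing covariate", rid)
            continue
        cov = Covariates(
            gestational_age=float(row["ga_days"]),
            birth_weight=float(row["birth_weight_g"]),
            delivery_mode=str(row["delivery_mode"]),
        )
        factor = 1.0 if unit == "umol_l" else UMOL_PER_MGDL
        ms = [
            Measurement(float(t), float(w) * factor)
            for t, w in zip(grp["pna_h"], grp[col])
            if not (pd.isna(t) or pd.isna(w))
        ]
        records.append(NeonateRecord(str(rid), cov, tuple(ms)))
    return records


def write_cohort(records: Iterable[NeonateRecord], path, unit: str = "umol_l") -> None:
    """Write a cohort to CSV in the schema read by :func:`read_cohort`."""
    col = _tsb_column(unit)
    factor = 1.0 if unit == "umol_l" else 1.0 / UMOL_PER_MGDL
    rows = []
    for rec in records:
        for m in rec.measurements:
            rows.append(
                {
                    "neonate_id": rec.record_id,
                    "ga_days": rec.covariates.gestational_age,
                    "birth_weight_g": rec.covariates.birth_weight,
                    "delivery_mode": rec.covariates.delivery_mode,
                    "pna_h": m.pna_h,
                    col: m.tsb * factor,
                }
            )
    # repr of a python float is the shortest string that round-trips exactly
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS) + [col]).to_csv(
        path, index=False, float_format=lambda v: repr(float(v))
    )


# ---------------------------------------------------------------------------
# Population-model parameter files (flat JSON, units in keys)
# ---------------------------------------------------------------------------

_THETA_KEYS = {
    "b0": "B0_umol_l",
    "p_ss": "Pss_umol_l_per_h",
    "a_p": "Ap",
    "t_p": "Tp_h",
    "k_ss": "Kss_per_h",
    "m_e": "Me",
    "t_e": "Te_h",
}


def save_model(model, path) -> None:
    """Write a PopulationModel to a flat JSON parameter file."""
    doc = {
        _THETA_KEYS[name]: getattr(model.theta_pop, name) for name in _THETA_KEYS
    }
    doc.update(
        {
            "sigma_prop": model.sigma_prop,
            "random_effect_names": list(model.random_effect_names),
            "omega": np.asarray(model.omega).tolist(),
            "beta_bw": model.beta.beta_bw,
            "beta_ga": model.beta.beta_ga,
            "beta_cs": model.beta.beta_cs,
            "ref_bw_g": model.beta.ref_bw,
            "ref_ga_days": model.beta.ref_ga,
        }
    )
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_model(path):
    """Read a PopulationModel from a parameter file written by save_model."""
    from .population import PopulationModel  # deferred: avoid cycle

    doc = json.loads(Path(path).read_text())
    theta = StructuralParameters(
        **{name: float(doc[key]) for name, key in _THETA_KEYS.items()}
    )
    beta = CovariateEffects(
        beta_bw=float(doc.get("beta_bw", 0.0)),
        beta_ga=float(doc.get("beta_ga", 0.0)),
        beta_cs=float(doc.get("beta_cs", 0.0)),
        ref_bw=float(doc.get("ref_bw_g", 2500.0)),
        ref_ga=float(doc.get("ref_ga_days", 265.0)),
    )
    return PopulationModel(
        theta_pop=theta,
        omega=np.asarray(doc["omega"], dtype=float),
        beta=beta,
        sigma_prop=float(doc["sigma_prop"]),
        random_effect_names=tuple(doc["random_effect_names"]),
    )
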