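"""Seeded synthetic ART cohorts with known generative truth.

The generator emulates the statistical structure of an urban treatment
program cohort: ~2,163 people across three regimens (first-line EFV;
second-line ATV/r and DTG), ~60% female, regimen-specific baseline age and
CD4 distributions, viral loads scheduled at weeks 12/24/48/72/96 with
date jitter and missed visits, a time-constant person-level random intercept
on the logit scale, calendar-driven administrative censoring (DTG was
introduced years later, so late-week measurements are scarcer), and rare
loss to follow-up / death.

Outcomes are generated by running the analysis model forward: per person one
intercept u ~ Normal(0, sigma_u^2); per attended week a suppression
indicator Bernoulli(expit(x'beta + u)), emitted as a numeric viral load
drawn from a suppressed (<50 copies/mL) or unsuppressed (>=50) range.
"""

from __future__ import annotations

import datetime as dt
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from vlsupp.errors import ConfigurationError
from vlsupp.model import ModelSpec, _encode

__all__ = [
    "SimulationConfig",
    "generate_cohort",
    "generate_outcomes",
    "write_dataset",
    "load_dataset",
    "simulate_dataset",
]

REGIMENS = ("EFV", "ATVr", "DTG")
WEEKS = (12, 24, 48, 72, 96)
AGE_GROUPS = ("12-19", "20-29", "30-39", "40+")
CD4_GROUPS = ("<200", "200-349", ">=350")

#: age range sampled uniformly within each group
_AGE_RANGES = {"12-19": (12, 19), "20-29": (20, 29), "30-39": (30, 39), "40+": (40, 75)}
#: CD4 range sampled uniformly within each group (cells/mm^3)
_CD4_RANGES = {"<200": (10, 199), "200-349": (200, 349), ">=350": (350, 900)}

#: calendar windows for baseline dates; DTG rolled out from mid-2019 only
_BASELINE_WINDOWS = {
    "EFV": (dt.date(2013, 2, 1), dt.date(2019, 6, 30)),
    "ATVr": (dt.date(2014, 1, 1), dt.date(2019, 6, 30)),
    "DTG": (dt.date(2019, 7, 1), dt.date(2021, 6, 30)),
}
_DB_CLOSURE = dt.date(2022, 8, 30)
_MAX_FOLLOWUP_DAYS = 700  # status assessed by week 100


def _default_true_beta() -> Dict[str, float]:
    """Generative coefficients (logit scale) chosen to emulate the observed
    suppression pattern: EFV rises to a high plateau by week 48, second-line
    regimens plateau lower, DTG suppresses fastest at week 12, suppression
    increases with age and CD4 and is lower in males."""
    beta = {
        "intercept": 0.0,
        "regimen=ATVr": -0.1,
        "regimen=DTG": 0.6,
        "week=24": 1.0,
        "week=48": 1.8,
        "week=72": 1.9,
        "week=96": 1.9,
        "sex=male": -0.35,
        "age_group=20-29": 0.3,
        "age_group=30-39": 0.6,
        "age_group=40+": 0.9,
        "cd4_group=200-349": 0.35,
        "cd4_group=>=350": 0.6,
        # second-line plateaus lower; DTG loses its early advantage
        "regimen=ATVr:week=24": -0.5,
        "regimen=ATVr:week=48": -1.1,
        "regimen=ATVr:week=72": -1.2,
        "regimen=ATVr:week=96": -1.2,
        "regimen=DTG:week=24": -1.0,
        "regimen=DTG:week=48": -1.6,
        "regimen=DTG:week=72": -1.7,
        "regimen=DTG:week=96": -1.7,
    }
    return beta


def _default_attendance() -> Dict[str, Dict[int, float]]:
    # probability a scheduled visit yields a VL measurement, conditional on
    # the person still being under follow-up at that week
    return {
        "EFV": {12: 0.76, 24: 0.84, 48: 0.78, 72: 0.41, 96: 0.62},
        "ATVr": {12: 0.78, 24: 0.83, 48: 0.76, 72: 0.58, 96: 0.66},
        "DTG": {12: 0.84, 24: 0.72, 48: 0.66, 72: 0.55, 96: 0.62},
    }


class SimulationConfig(BaseModel):
    """Full specification of a synthetic cohort (validated)."""

    model_config = ConfigDict(extra="forbid")

    n_per_regimen: Dict[str, int] = Field(
        default_factory=lambda: {"EFV": 1049, "ATVr": 872, "DTG": 242}
    )
    prob_female: float = 0.599
    age_group_probs: Dict[str, Tuple[float, float, float, float]] = Field(
        default_factory=lambda: {
            "EFV": (0.092, 0.193, 0.332, 0.383),
            "ATVr": (0.257, 0.251, 0.185, 0.307),
            "DTG": (0.277, 0.240, 0.202, 0.281),
        }
    )
    cd4_group_probs: Dict[str, Tuple[float, float, float]] = Field(
        default_factory=lambda: {
            "EFV": (0.406, 0.316, 0.278),
            "ATVr": (0.529, 0.251, 0.220),
            "DTG": (0.405, 0.211, 0.384),
        }
    )
    true_beta: Dict[str, float] = Field(default_factory=_default_true_beta)
    sigma_u: float = 1.0
    attendance_prob: Dict[str, Dict[int, float]] = Field(
        default_factory=_default_attendance
    )
    jitter_sd: float = 7.0
    out_of_window_prob: float = 0.05
    suppressed_vl_range: Tuple[float, float] = (0, 49)
    unsuppressed_vl_range: Tuple[float, float] = (200, 100_000)
    censor_week: Dict[str, int] = Field(
        default_factory=lambda: {"EFV": 96, "ATVr": 96, "DTG": 96}
    )
    ltfu_prob: float = 0.0
    death_prob: float = 0.0
    seed: int = 0

    @field_validator("prob_female", "out_of_window_prob", "ltfu_prob", "death_prob")
    @classmethod
    def _prob01(cls, v, info):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{info.field_name} must be in [0, 1], got {v}")
        return v

    @field_validator("sigma_u")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError(f"sigma_u must be >= 0, got {v}")
        return v

    @field_validator("jitter_sd")
    @classmethod
    def _jitter(cls, v):
        if v < 0:
            raise ValueError(f"jitter_sd must be >= 0, got {v}")
        return v

    @field_validator("n_per_regimen")
    @classmethod
    def _counts(cls, v):
        if set(v) != set(REGIMENS):
            raise ValueError(f"n_per_regimen must have keys {REGIMENS}, got {sorted(v)}")
        for k, n in v.items():
            if n < 0:
                raise ValueError(f"n_per_regimen[{k}] must be >= 0, got {n}")
        return v

    @field_validator("age_group_probs", "cd4_group_probs")
    @classmethod
    def _dists(cls, v, info):
        if set(v) != set(REGIMENS):
            raise ValueError(f"{info.field_name} must have keys {REGIMENS}")
        for k, probs in v.items():
            if any(p < 0 for p in probs):
                raise ValueError(f"{info.field_name}[{k}] has negative probabilities")
            if abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError(
                    f"{info.field_name}[{k}] must sum to 1, got {sum(probs)}"
                )
        return v

    @field_validator("attendance_prob")
    @classmethod
    def _attendance(cls, v, info):
        if set(v) != set(REGIMENS):
            raise ValueError("attendance_prob must have keys " + str(REGIMENS))
        for k, per_week in v.items():
            if set(per_week) != set(WEEKS):
                raise ValueError(
                    f"attendance_prob[{k}] must have week keys {WEEKS}"
                )
            for w, p in per_week.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"attendance_prob[{k}][{w}] must be in [0, 1], got {p}"
                    )
        return v

    @field_validator("censor_week")
    @classmethod
    def _censor(cls, v):
        if set(v) != set(REGIMENS):
            raise ValueError("censor_week must have keys " + str(REGIMENS))
        for k, w in v.items():
            if w <= 0:
                raise ValueError(f"censor_week[{k}] must be > 0, got {w}")
        return v

    @model_validator(mode="after")
    def _ranges(self):
        lo, hi = self.suppressed_vl_range
        if not (0 <= lo <= hi < 50):
            raise ValueError(
                f"suppressed_vl_range must lie within [0, 50), got {(lo, hi)}"
            )
        lo, hi = self.unsuppressed_vl_range
        if not (50 <= lo <= hi):
            raise ValueError(
                f"unsuppressed_vl_range must lie within [50, inf), got {(lo, hi)}"
            )
        if self.ltfu_prob + self.death_prob > 1.0:
            raise ValueError("ltfu_prob + death_prob must be <= 1")
        return self


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw baseline records: one row per person.

    Columns: person_id, sex, age_years, cd4_cells, regimen, line,
    baseline_date, end_status, end_date. Deterministic given the config seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    rows = []
    k = 0
    for reg in REGIMENS:
        n = config.n_per_regimen[reg]
        line = "first" if reg == "EFV" else "second"
        agp = np.asarray(config.age_group_probs[reg], dtype=float)
        cdp = np.asarray(config.cd4_group_probs[reg], dtype=float)
        start, stop = _BASELINE_WINDOWS[reg]
        span = (stop - start).days
        for _ in range(n):
            k += 1
            sex = "female" if rng.random() < config.prob_female else "male"
            ag = AGE_GROUPS[rng.choice(len(AGE_GROUPS), p=agp / agp.sum())]
            cg = CD4_GROUPS[rng.choice(len(CD4_GROUPS), p=cdp / cdp.sum())]
            age = int(rng.integers(_AGE_RANGES[ag][0], _AGE_RANGES[ag][1] + 1))
            cd4 = int(rng.integers(_CD4_RANGES[cg][0], _CD4_RANGES[cg][1] + 1))
            baseline = start + dt.timedelta(days=int(rng.integers(0, span + 1)))
            admin_days = min(_MAX_FOLLOWUP_DAYS, (_DB_CLOSURE - baseline).days)
            r = rng.random()
            if r < config.ltfu_prob:
                status = "ltfu"
                end_days = int(rng.integers(1, _MAX_FOLLOWUP_DAYS + 1))
                end_days = min(end_days, admin_days)
            elif r < config.ltfu_prob + config.death_prob:
                status = "dead"
                end_days = int(rng.integers(1, _MAX_FOLLOWUP_DAYS + 1))
                end_days = min(end_days, admin_days)
            else:
                status = "in_care"
                end_days = admin_days
            rows.append(
                {
                    "person_id": f"P{k:06d}",
                    "sex": sex,
                    "age_years": age,
                    "cd4_cells": cd4,
                    "regimen": reg,
                    "line": line,
                    "baseline_date": baseline.isoformat(),
                    "end_status": status,
                    "end_date": (baseline + dt.timedelta(days=end_days)).isoformat(),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "person_id", "sex", "age_years", "cd4_cells", "regimen", "line",
            "baseline_date", "end_status", "end_date",
        ],
    )


def _bin_age(age: np.ndarray) -> np.ndarray:
    return np.select(
        [age <= 19, age <= 29, age <= 39], ["12-19", "20-29", "30-39"], "40+"
    )


def _bin_cd4(cd4: np.ndarray) -> np.ndarray:
    return np.select([cd4 < 200, cd4 < 350], ["<200", "200-349"], ">=350")


def _linear_predictor(frame: pd.DataFrame, true_beta: Dict[str, float]) -> np.ndarray:
    """x'beta for rows with columns regimen/week/sex/age_group/cd4_group.

    The coefficient vector is named by design-column; every design column
    implied by the covariates (with the week-by-regimen interaction) must be
    present in ``true_beta``, and no unknown names are allowed.
    """
    spec = ModelSpec(interactions=(("regimen", "week"),))
    X, cols = _encode(frame, spec)
    missing = [c for c in cols if c not in true_beta]
    if missing:
        raise ConfigurationError(f"true_beta lacks coefficients for {missing}")
    unknown = [c for c in true_beta if c not in cols]
    if unknown:
        raise ConfigurationError(f"true_beta has unknown coefficient names {unknown}")
    beta = np.array([true_beta[c] for c in cols])
    return X @ beta


def generate_outcomes(cohort: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Draw dated viral-load measurements by running the model forward.

    One row per attended visit: person_id, sample_date, vl_copies_per_ml.
    A visit at scheduled week w lands on day 7w plus Normal(0, jitter_sd)
    jitter (rounded to days), or — with probability ``out_of_window_prob`` —
    a uniform out-of-window shift of 29..56 days in either direction, so the
    downstream imputation path is exercised. No measurement is emitted after
    the regimen's administrative censor week or the person's end of follow-up.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = len(cohort)
    u = rng.normal(0.0, config.sigma_u, size=n) if config.sigma_u > 0 else np.zeros(n)

    # per-person-week linear predictors, computed in one design pass
    weeks = np.array(WEEKS)
    rep = cohort.loc[cohort.index.repeat(len(weeks))].reset_index(drop=True)
    rep["week"] = np.tile(weeks, n)
    rep["age_group"] = _bin_age(rep["age_years"].to_numpy())
    rep["cd4_group"] = _bin_cd4(rep["cd4_cells"].to_numpy())
    eta = _linear_predictor(rep, config.true_beta) + np.repeat(u, len(weeks))
    p_supp = 1.0 / (1.0 + np.exp(-eta))

    s_lo, s_hi = config.suppressed_vl_range
    u_lo, u_hi = config.unsuppressed_vl_range
    baseline_ts = pd.to_datetime(cohort["baseline_date"])
    baseline = baseline_ts.dt.date.to_numpy()
    followup_days = (
        (pd.to_datetime(cohort["end_date"]) - baseline_ts).dt.days.to_numpy()
    )

    rows = []
    idx = 0
    for i in range(n):
        reg = cohort["regimen"].iat[i]
        att = config.attendance_prob[reg]
        cw = config.censor_week[reg]
        seen_days = set()
        for j, w in enumerate(WEEKS):
            pj = p_supp[idx + j]
            if w > cw:
                continue
            day = 7 * w
            if rng.random() >= att[w]:
                continue
            if config.out_of_window_prob > 0 and rng.random() < config.out_of_window_prob:
                shift = int(rng.integers(29, 57))
                day += shift if rng.random() < 0.5 else -shift
            elif config.jitter_sd > 0:
                day += int(round(rng.normal(0.0, config.jitter_sd)))
            if day < 1 or day > followup_days[i] or day in seen_days:
                continue
            seen_days.add(day)
            suppressed = rng.random() < pj
            if suppressed:
                vl = int(rng.integers(int(s_lo), int(s_hi) + 1))
            else:
                vl = int(rng.integers(int(u_lo), int(u_hi) + 1))
            rows.append(
                {
                    "person_id": cohort["person_id"].iat[i],
                    "sample_date": (
                        baseline[i] + dt.timedelta(days=day)
                    ).isoformat(),
                    "vl_copies_per_ml": vl,
                }
            )
        idx += len(WEEKS)
    return pd.DataFrame(
        rows, columns=["person_id", "sample_date", "vl_copies_per_ml"]
    )


def write_dataset(cohort: pd.DataFrame, measurements: pd.DataFrame, outdir) -> dict:
    """Write persons.csv / viral_loads.csv; returns the two paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    extra = set(measurements["person_id"]) - set(cohort["person_id"])
    if extra:
        raise ConfigurationError(
            f"measurements reference unknown person_ids, e.g. {sorted(extra)[:3]}"
        )
    persons_path = outdir / "persons.csv"
    vl_path = outdir / "viral_loads.csv"
    cohort.to_csv(persons_path, index=False)
    measurements.to_csv(vl_path, index=False)
    return {"persons": persons_path, "viral_loads": vl_path}


def load_dataset(indir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read persons.csv / viral_loads.csv back as written."""
    from pathlib import Path

    indir = Path(indir)
    persons = pd.read_csv(indir / "persons.csv", dtype={"person_id": str})
    vl = pd.read_csv(indir / "viral_loads.csv", dtype={"person_id": str})
    return persons, vl


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: cohort + outcomes in one call."""
    cohort = generate_cohort(config)
    return cohort, generate_outcomes(cohort, config)
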