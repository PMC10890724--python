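"""From raw cohort + viral-load tables to the per-week binary analysis table.

The pipeline is: inclusion filtering (age >= 12, >= 24 weeks = 168 days of
follow-up), assignment of dated measurements to scheduled visit windows
(week w covers days 7w +/- 28; one month is read as exactly four weeks),
nearest-to-centre selection when several measurements fall in one window,
"sandwich" imputation of missing windows (imputed only when the nearest
measurements strictly before and strictly after the window agree on the
<50 copies/mL dichotomy, so no viral blip can be created by imputation),
and binning of baseline age and CD4 count into the analysis categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from vlsupp.errors import ContractViolationError, DataValidationError

__all__ = [
    "WEEKS",
    "HALF_WIDTH_DAYS",
    "InclusionReport",
    "PrepReport",
    "apply_inclusion",
    "assign_windows",
    "select_nearest",
    "sandwich_impute",
    "dichotomize",
    "bin_age",
    "bin_cd4",
    "bin_covariates",
    "build_analysis_table",
    "measurements_to_days",
]

WEEKS: tuple[int, ...] = (12, 24, 48, 72, 96)
HALF_WIDTH_DAYS: int = 28          # "one-month" window = +/- 4 weeks
MIN_AGE_YEARS: int = 12
MIN_FOLLOWUP_DAYS: int = 168       # 24 weeks
SUPPRESSION_THRESHOLD: float = 50.0


@dataclass
class InclusionReport:
    n_input: int
    n_excluded_age: int
    n_excluded_followup: int

    @property
    def n_included(self) -> int:
        return self.n_input - self.n_excluded_age - self.n_excluded_followup


def apply_inclusion(
    cohort: pd.DataFrame,
    min_age: int = MIN_AGE_YEARS,
    min_followup_days: int = MIN_FOLLOWUP_DAYS,
) -> tuple[pd.DataFrame, InclusionReport]:
    """Keep persons aged >= 12 at baseline with >= 168 days of follow-up.

    Already-included-only cohorts pass through unchanged (idempotent).
    """
    if cohort["baseline_date"].isna().any():
        bad = cohort.loc[cohort["baseline_date"].isna(), "person_id"].tolist()
        raise DataValidationError(f"missing baseline_date for persons {bad[:5]}")
    if cohort["end_date"].isna().any():
        bad = cohort.loc[cohort["end_date"].isna(), "person_id"].tolist()
        raise DataValidationError(f"missing end_date for persons {bad[:5]}")
    followup = (
        pd.to_datetime(cohort["end_date"]) - pd.to_datetime(cohort["baseline_date"])
    ).dt.days
    if (followup < 0).any():
        raise DataValidationError("end_date precedes baseline_date for some persons")
    ok_age = cohort["age_years"] >= min_age
    ok_fup = followup >= min_followup_days
    report = InclusionReport(
        n_input=len(cohort),
        n_excluded_age=int((~ok_age).sum()),
        n_excluded_followup=int((ok_age & ~ok_fup).sum()),
    )
    return cohort.loc[ok_age & ok_fup].reset_index(drop=True), report


def assign_windows(
    days: np.ndarray,
    weeks: tuple[int, ...] = WEEKS,
    half_width_days: int = HALF_WIDTH_DAYS,
) -> np.ndarray:
    """Map measurement days to scheduled weeks; -1 where unassigned.

    Day d belongs to week w iff |d - 7w| <= half_width_days. Windows are
    disjoint for the default schedule (gaps exist, e.g. days 197-307 between
    the week-24 and week-48 windows); a day in a gap — such as day 245, i.e.
    week 35 — stays unassigned, as do early/baseline days.
    """
    days = np.asarray(days)
    out = np.full(days.shape, -1, dtype=np.int64)
    for w in weeks:
        hit = np.abs(days - 7 * w) <= half_width_days
        out[hit] = w
    return out


def select_nearest(measurements: pd.DataFrame, week: int) -> pd.Series | None:
    """Pick one person's measurement closest to the week centre (day 7w).

    Ties are broken toward the earlier day. Returns None when no measurement
    is assigned to the window.
    """
    if len(measurements) == 0:
        return None
    dist = (measurements["day"] - 7 * week).abs()
    order = np.lexsort((measurements["day"].to_numpy(), dist.to_numpy()))
    return measurements.iloc[order[0]]


def dichotomize(vl) -> np.ndarray | int:
    """1 iff viral load < 50 copies/mL (strict), else 0."""
    arr = np.asarray(vl, dtype=float)
    if (arr < 0).any():
        raise DataValidationError("viral load must be >= 0 copies/mL")
    out = (arr < SUPPRESSION_THRESHOLD).astype(np.int64)
    return out if out.shape else int(out)


def bin_age(age) -> np.ndarray | str:
    """Closed bins 12-19 / 20-29 / 30-39 / 40+ (validates age >= 12)."""
    arr = np.asarray(age)
    if (arr < MIN_AGE_YEARS).any():
        raise DataValidationError("age below 12 should have been excluded")
    out = np.select([arr <= 19, arr <= 29, arr <= 39], ["12-19", "20-29", "30-39"], "40+")
    return out if out.shape else str(out)


def bin_cd4(cd4) -> np.ndarray | str:
    """Closed bins <200 / 200-349 / >=350 cells/mm^3."""
    arr = np.asarray(cd4)
    if (arr < 0).any():
        raise DataValidationError("CD4 count must be >= 0")
    out = np.select([arr < 200, arr < 350], ["<200", "200-349"], ">=350")
    return out if out.shape else str(out)


def bin_covariates(record: pd.Series) -> tuple[str, str]:
    """(age_group, cd4_group) for one baseline record."""
    return bin_age(record["age_years"]), bin_cd4(record["cd4_cells"])


def sandwich_impute(
    person_measurements: pd.DataFrame,
    week: int,
    half_width_days: int = HALF_WIDTH_DAYS,
) -> int | None:
    """Impute the missing window status from its flanking measurements.

    Candidate neighbours are any of the person's measurements (in- or
    out-of-window) with day strictly before the window start or strictly
    after the window end; baseline measurements (day <= 0) never qualify.
    The nearest neighbour on each side is used. Returns the shared 0/1
    status when both exist and agree on the <50 dichotomy, else None —
    discordant neighbours are never resolved, so no viral blip (or its
    inverse) can be imputed.
    """
    lo, hi = 7 * week - half_width_days, 7 * week + half_width_days
    days = person_measurements["day"].to_numpy()
    if ((days >= lo) & (days <= hi)).any():
        raise ContractViolationError(
            f"sandwich_impute called for week {week} but an in-window "
            "measurement exists"
        )
    usable = person_measurements.loc[person_measurements["day"] > 0]
    before = usable.loc[usable["day"] < lo]
    after = usable.loc[usable["day"] > hi]
    if len(before) == 0 or len(after) == 0:
        return None
    vb = before.loc[before["day"].idxmax(), "vl"]
    va = after.loc[after["day"].idxmin(), "vl"]
    sb, sa = dichotomize(vb), dichotomize(va)
    return int(sb) if sb == sa else None


def measurements_to_days(
    cohort: pd.DataFrame, measurements: pd.DataFrame
) -> pd.DataFrame:
    """Convert dated viral loads to (person_id, day, vl) day offsets."""
    base = cohort.set_index("person_id")["baseline_date"]
    unknown = set(measurements["person_id"]) - set(base.index)
    if unknown:
        raise DataValidationError(
            f"measurements reference persons absent from cohort, e.g. "
            f"{sorted(unknown)[:3]}"
        )
    day = (
        pd.to_datetime(measurements["sample_date"]).to_numpy()
        - pd.to_datetime(measurements["person_id"].map(base)).to_numpy()
    ).astype("timedelta64[D]").astype(np.int64)
    out = pd.DataFrame(
        {
            "person_id": measurements["person_id"].to_numpy(),
            "day": day,
            "vl": measurements["vl_copies_per_ml"].to_numpy(),
        }
    )
    dup = out.duplicated(["person_id", "day"])
    if dup.any():
        raise DataValidationError(
            "multiple viral loads on the same day for persons "
            f"{out.loc[dup, 'person_id'].unique()[:3].tolist()}"
        )
    return out


@dataclass
class PrepReport:
    """Counts logged while building the analysis table."""

    inclusion: InclusionReport
    n_measurements: int = 0
    n_assigned: int = 0
    n_unassigned: int = 0
    n_observed_rows: int = 0
    n_imputed_rows: int = 0
    complete_case: bool = False

    @property
    def n_rows(self) -> int:
        return self.n_observed_rows + self.n_imputed_rows


def build_analysis_table(
    cohort: pd.DataFrame,
    measurements: pd.DataFrame,
    complete_case: bool = False,
    weeks: tuple[int, ...] = WEEKS,
    half_width_days: int = HALF_WIDTH_DAYS,
) -> tuple[pd.DataFrame, PrepReport]:
    """Compose inclusion, window assignment, selection and imputation.

    Returns one row per (person, week) with an observed or imputed binary
    suppression status, plus a report with the observed/imputed counts.
    With ``complete_case=True`` the imputed rows are dropped (sensitivity
    analysis); everything else is unchanged.
    """
    included, inclusion = apply_inclusion(cohort)
    report = PrepReport(inclusion=inclusion, complete_case=complete_case)

    measurements = measurements.loc[
        measurements["person_id"].isin(set(included["person_id"]))
    ]
    mt = measurements_to_days(included, measurements)
    report.n_measurements = len(mt)
    mt = mt.assign(week=assign_windows(mt["day"].to_numpy(), weeks, half_width_days))
    report.n_assigned = int((mt["week"] > 0).sum())
    report.n_unassigned = len(mt) - report.n_assigned

    covars = included.set_index("person_id")
    age_g = bin_age(covars["age_years"].to_numpy())
    cd4_g = bin_cd4(covars["cd4_cells"].to_numpy())
    covars = pd.DataFrame(
        {
            "sex": covars["sex"],
            "age_group": age_g,
            "cd4_group": cd4_g,
            "regimen": covars["regimen"],
        },
        index=covars.index,
    )

    rows = []
    by_person = dict(tuple(mt.groupby("person_id", sort=False)))
    for pid in included["person_id"]:
        pm = by_person.get(pid)
        if pm is None:
            continue
        for w in weeks:
            inwin = pm.loc[pm["week"] == w]
            if len(inwin):
                chosen = select_nearest(inwin, w)
                rows.append(
                    (pid, w, int(dichotomize(chosen["vl"])), "observed",
                     int(chosen["day"]))
                )
            else:
                status = sandwich_impute(pm, w, half_width_days)
                if status is not None:
                    rows.append((pid, w, status, "imputed", pd.NA))
    table = pd.DataFrame(
        rows, columns=["person_id", "week", "suppressed", "provenance", "source_day"]
    )
    report.n_observed_rows = int((table["provenance"] == "observed").sum())
    report.n_imputed_rows = int((table["provenance"] == "imputed").sum())
    if complete_case:
        table = table.loc[table["provenance"] == "observed"].reset_index(drop=True)
    table = table.join(covars, on="person_id")
    table["source_day"] = table["source_day"].astype("Int64")
    return table.reset_index(drop=True), report
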