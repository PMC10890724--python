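"""Population-averaged (marginalized) effects from the posterior draws.

The fitted model is conditional on the person intercept u. All reported
quantities integrate the conditional success probability over the
population random-effect distribution, per posterior draw s:

    p(eta, sigma) = E_u[ expit(eta + u) ],  u ~ Normal(0, sigma^2)

evaluated by Gauss-Hermite quadrature. Marginal odds ratios are ratios of
the so-marginalized odds and are therefore attenuated relative to the
conditional (cluster-specific) odds ratios. Standardized predictions follow
the g-computation recipe: predict a counterfactual regimen for *every*
person in the analysis population at each week and average; non-standardized
predictions average only over the persons actually observed in each
(week, regimen) stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import beta as beta_dist

from vlsupp.errors import DataValidationError
from vlsupp.model import ModelSpec, PosteriorSample, design_row

__all__ = [
    "CovariateProfile",
    "MarginalEstimate",
    "marginal_probability",
    "marginal_aor",
    "standardized_predictions",
    "nonstandardized_predictions",
    "crude_proportion",
    "crude_proportions_table",
    "estimates_to_frame",
]

GH_NODES_DEFAULT = 31
_P_CLAMP = 1e-12


@dataclass(frozen=True)
class CovariateProfile:
    """One prediction stratum of the fitted design."""

    regimen: str
    week: int
    sex: str
    age_group: str
    cd4_group: str

    def as_dict(self) -> dict:
        return {
            "regimen": self.regimen,
            "week": self.week,
            "sex": self.sex,
            "age_group": self.age_group,
            "cd4_group": self.cd4_group,
        }


@dataclass
class MarginalEstimate:
    """Posterior median and central 95% interval of an aOR or proportion."""

    kind: str                      # "aOR" | "proportion"
    point: float
    lower: float
    upper: float
    standardized: bool | None
    labels: dict
    n_draws: int


def _gh_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    return z, w / np.sqrt(np.pi)


def marginal_probability(
    eta, sigma_u, n_nodes: int = GH_NODES_DEFAULT
) -> np.ndarray | float:
    """E_u[expit(eta + u)] for u ~ Normal(0, sigma_u^2), by Gauss-Hermite.

    Broadcasts over ``eta`` and ``sigma_u``; collapses exactly to
    expit(eta) at sigma_u = 0, and equals 1/2 at eta = 0 for any sigma_u.
    """
    eta = np.asarray(eta, dtype=float)
    sigma = np.asarray(sigma_u, dtype=float)
    if not np.isfinite(eta).all():
        raise DataValidationError("non-finite linear predictor")
    if (sigma < 0).any():
        raise DataValidationError("sigma_u must be >= 0")
    eta_b, sigma_b = np.broadcast_arrays(eta, sigma)
    z, w = _gh_nodes(n_nodes)
    # change of variables u = sqrt(2) * sigma * z
    vals = expit(eta_b[..., None] + np.sqrt(2.0) * sigma_b[..., None] * z)
    out = vals @ w
    out = np.where(sigma_b == 0.0, expit(eta_b), out)
    return out if out.shape else float(out)


def _summarize(draws: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.median(draws)),
        float(np.quantile(draws, 0.025)),
        float(np.quantile(draws, 0.975)),
    )


def _profile_eta(sample: PosteriorSample, profile: CovariateProfile) -> np.ndarray:
    x = design_row(profile.as_dict(), sample.spec)
    return sample.beta @ x


def marginal_aor(
    sample: PosteriorSample,
    profile_a: CovariateProfile,
    profile_b: CovariateProfile,
    n_nodes: int = GH_NODES_DEFAULT,
) -> MarginalEstimate:
    """Marginal adjusted odds ratio of profile_a versus profile_b.

    Per draw, both profiles' marginal probabilities share that draw's
    sigma_u; the odds ratio of the marginalized probabilities is summarized
    by its posterior median and central 95% interval.
    """
    eta_a = _profile_eta(sample, profile_a)
    eta_b = _profile_eta(sample, profile_b)
    p_a = marginal_probability(eta_a, sample.sigma_u, n_nodes)
    p_b = marginal_probability(eta_b, sample.sigma_u, n_nodes)
    clip_needed = (
        (p_a <= 0).any() or (p_a >= 1).any() or (p_b <= 0).any() or (p_b >= 1).any()
    )
    if clip_needed:
        warnings.warn("marginal probabilities at 0/1 clamped for odds computation")
        p_a = np.clip(p_a, _P_CLAMP, 1 - _P_CLAMP)
        p_b = np.clip(p_b, _P_CLAMP, 1 - _P_CLAMP)
    ors = (p_a / (1 - p_a)) / (p_b / (1 - p_b))
    point, lo, hi = _summarize(ors)
    return MarginalEstimate(
        kind="aOR",
        point=point,
        lower=lo,
        upper=hi,
        standardized=None,
        labels={"a": profile_a.as_dict(), "b": profile_b.as_dict()},
        n_draws=sample.n_draws,
    )


def _person_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """One baseline covariate row per person appearing in the table."""
    cols = ["person_id", "sex", "age_group", "cd4_group"]
    persons = table[cols].drop_duplicates()
    if persons["person_id"].duplicated().any():
        raise DataValidationError("inconsistent baseline covariates within person")
    return persons.reset_index(drop=True)


def _weighted_profiles(persons: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    counts = (
        persons.groupby(["sex", "age_group", "cd4_group"], observed=True)
        .size()
        .reset_index(name="n")
    )
    w = counts["n"].to_numpy(dtype=float)
    return counts, w / w.sum()


def _averaged_prediction(
    sample: PosteriorSample,
    covariate_rows: pd.DataFrame,
    weights: np.ndarray,
    week: int,
    regimen: str,
    n_nodes: int,
) -> np.ndarray:
    """Weighted mean over covariate profiles of the marginal probability,
    per posterior draw. Returns (S,) draws of the averaged proportion."""
    rows = np.stack(
        [
            design_row(
                {
                    "regimen": regimen,
                    "week": week,
                    "sex": r.sex,
                    "age_group": r.age_group,
                    "cd4_group": r.cd4_group,
                },
                sample.spec,
            )
            for r in covariate_rows.itertuples()
        ]
    )
    eta = rows @ sample.beta.T                     # (K, S)
    probs = marginal_probability(eta, sample.sigma_u[None, :], n_nodes)
    return weights @ probs


def standardized_predictions(
    sample: PosteriorSample,
    table: pd.DataFrame,
    weeks=None,
    regimens=None,
    n_nodes: int = GH_NODES_DEFAULT,
) -> list[MarginalEstimate]:
    """g-computation: every person predicted under every regimen and week.

    The averaging population is the full set of persons in the analysis
    table, so regimen contrasts are standardized to a common covariate
    distribution.
    """
    if len(table) == 0:
        raise DataValidationError("empty analysis table")
    spec: ModelSpec = sample.spec
    weeks = list(weeks) if weeks is not None else list(spec.term("week").levels)
    regimens = (
        list(regimens) if regimens is not None else list(spec.term("regimen").levels)
    )
    persons = _person_covariates(table)
    profiles, weights = _weighted_profiles(persons)
    out = []
    for week in weeks:
        for reg in regimens:
            draws = _averaged_prediction(sample, profiles, weights, week, reg, n_nodes)
            point, lo, hi = _summarize(draws)
            out.append(
                MarginalEstimate(
                    kind="proportion",
                    point=point,
                    lower=lo,
                    upper=hi,
                    standardized=True,
                    labels={"week": week, "regimen": reg},
                    n_draws=sample.n_draws,
                )
            )
    return out


def nonstandardized_predictions(
    sample: PosteriorSample,
    table: pd.DataFrame,
    n_nodes: int = GH_NODES_DEFAULT,
) -> list[MarginalEstimate]:
    """Predictions averaged over the observed data only: each (week, regimen)
    stratum averages the persons who contributed an observation there, under
    their actual regimen. Empty strata are omitted with a warning."""
    if len(table) == 0:
        raise DataValidationError("empty analysis table")
    spec: ModelSpec = sample.spec
    out = []
    for week in spec.term("week").levels:
        for reg in spec.term("regimen").levels:
            stratum = table.loc[(table["week"] == week) & (table["regimen"] == reg)]
            if len(stratum) == 0:
                warnings.warn(f"no observations for week {week}, regimen {reg}; omitted")
                continue
            profiles, weights = _weighted_profiles(_person_covariates(stratum))
            draws = _averaged_prediction(sample, profiles, weights, week, reg, n_nodes)
            point, lo, hi = _summarize(draws)
            out.append(
                MarginalEstimate(
                    kind="proportion",
                    point=point,
                    lower=lo,
                    upper=hi,
                    standardized=False,
                    labels={"week": week, "regimen": reg, "n_persons": len(stratum)},
                    n_draws=sample.n_draws,
                )
            )
    return out


def crude_proportion(k: int, n: int) -> MarginalEstimate:
    """Crude proportion k/n with a Beta(k+1, n-k+1) central 95% interval
    (uniform prior on the proportion; within-person clustering ignored)."""
    if n < 1:
        raise DataValidationError("crude proportion needs n >= 1")
    if not 0 <= k <= n:
        raise DataValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    lo, hi = beta_dist.ppf([0.025, 0.975], k + 1, n - k + 1)
    return MarginalEstimate(
        kind="proportion",
        point=k / n,
        lower=float(lo),
        upper=float(hi),
        standardized=None,
        labels={"k": k, "n": n},
        n_draws=0,
    )


def crude_proportions_table(table: pd.DataFrame) -> list[MarginalEstimate]:
    """Crude suppression per (week, regimen) stratum of an analysis table."""
    out = []
    for (week, reg), grp in table.groupby(["week", "regimen"], observed=True):
        est = crude_proportion(int(grp["suppressed"].sum()), len(grp))
        est.labels = {"week": int(week), "regimen": reg, **est.labels}
        out.append(est)
    return out


def estimates_to_frame(estimates: list[MarginalEstimate]) -> pd.DataFrame:
    """Flatten estimates into the persisted estimates.csv layout."""
    rows = []
    for e in estimates:
        labels = e.labels
        if e.kind == "aOR":
            a, b = labels["a"], labels["b"]
            diff = [k for k in a if a[k] != b[k]]
            contrast = "; ".join(f"{k}: {a[k]} vs {b[k]}" for k in diff) or "identity"
            week = a["week"] if a.get("week") == b.get("week") else ""
            regimen = ""
        else:
            contrast = ""
            week = labels.get("week", "")
            regimen = labels.get("regimen", "")
        rows.append(
            {
                "kind": e.kind,
                "standardized": "" if e.standardized is None else e.standardized,
                "week": week,
                "regimen": regimen,
                "contrast": contrast,
                "point": e.point,
                "lower": e.lower,
                "upper": e.upper,
                "n_draws": e.n_draws,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "kind", "standardized", "week", "regimen", "contrast",
            "point", "lower", "upper", "n_draws",
        ],
    )
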