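"""Bayesian random-intercept logistic regression via Pólya-Gamma Gibbs.

The analysis model for repeated binary suppression outcomes is

    y_j | beta, u ~ Bernoulli(expit(x_j' beta + u_{i(j)}))
    u_i | sigma_u ~ Normal(0, sigma_u^2)        (one intercept per person)
    beta_p       ~ Normal(0, coef_prior_scale^2)
    sigma_u      ~ half-Normal(re_sd_prior)

Fixed effects are treatment regimen, visit week, sex, baseline age group and
baseline CD4 group (all categorical, treatment/dummy coded against declared
reference levels), optionally with two-way interactions.

Sampling uses Pólya-Gamma data augmentation (Polson, Scott & Windle 2013):
conditional on omega_j ~ PG(1, eta_j) the updates for ``beta`` and ``u`` are
conjugate Gaussians, and ``sigma_u`` is updated by a univariate slice
sampler under its half-Normal prior. The sampler is exact (no Metropolis
correction needed) and mixes well for this model class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from vlsupp._pg import pg_draw, seed_pg
from vlsupp.errors import ConfigurationError, DataValidationError, RankDeficiencyError

__all__ = [
    "Term",
    "ModelSpec",
    "DesignMatrix",
    "PosteriorSample",
    "Diagnostics",
    "DEFAULT_TERMS",
    "build_design",
    "design_row",
    "fit_posterior",
    "diagnose",
]


@dataclass(frozen=True)
class Term:
    """A categorical fixed effect; ``levels[0]`` is the reference level."""

    name: str
    levels: tuple

    def __post_init__(self):
        if len(self.levels) < 2:
            raise ConfigurationError(
                f"term {self.name!r} needs >= 2 levels (single-level terms are "
                "aliased with the intercept)"
            )
        if len(set(self.levels)) != len(self.levels):
            raise ConfigurationError(f"term {self.name!r} has duplicate levels")


#: Default covariate set: regimen, visit week, sex, baseline age and CD4
#: groups with the references chosen so regimen/time contrasts read directly
#: against first-line EFV at week 12.
DEFAULT_TERMS: tuple[Term, ...] = (
    Term("regimen", ("EFV", "ATVr", "DTG")),
    Term("week", (12, 24, 48, 72, 96)),
    Term("sex", ("female", "male")),
    Term("age_group", ("12-19", "20-29", "30-39", "40+")),
    Term("cd4_group", ("<200", "200-349", ">=350")),
)


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure and prior scales of the analysis model."""

    fixed_terms: tuple[Term, ...] = DEFAULT_TERMS
    interactions: tuple[tuple[str, str], ...] = ()
    coef_prior_scale: float = 2.5
    re_sd_prior: float = 1.0

    def __post_init__(self):
        names = [t.name for t in self.fixed_terms]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate fixed-term names")
        norm = []
        for pair in self.interactions:
            a, b = pair
            if a not in names or b not in names:
                raise ConfigurationError(
                    f"interaction {pair!r} references a term that is not a fixed term"
                )
            if a == b:
                raise ConfigurationError(f"interaction {pair!r} repeats a term")
            # store each unordered pair in fixed-term order, deduplicated
            if names.index(a) > names.index(b):
                a, b = b, a
            if (a, b) not in norm:
                norm.append((a, b))
        object.__setattr__(self, "interactions", tuple(norm))
        if self.coef_prior_scale <= 0:
            raise ConfigurationError("coef_prior_scale must be > 0")
        if self.re_sd_prior <= 0:
            raise ConfigurationError("re_sd_prior must be > 0")

    def term(self, name: str) -> Term:
        for t in self.fixed_terms:
            if t.name == name:
                return t
        raise ConfigurationError(f"unknown term {name!r}")

    def with_interactions(self, interactions) -> "ModelSpec":
        return replace(self, interactions=tuple(interactions))

    def column_names(self) -> list[str]:
        """Deterministic design-column names: intercept, mains, interactions."""
        cols = ["intercept"]
        for t in self.fixed_terms:
            cols += [f"{t.name}={lv}" for lv in t.levels[1:]]
        for a, b in self.interactions:
            ta, tb = self.term(a), self.term(b)
            cols += [
                f"{a}={la}:{b}={lb}"
                for la in ta.levels[1:]
                for lb in tb.levels[1:]
            ]
        return cols


@dataclass
class DesignMatrix:
    """Dummy-coded design aligned with an analysis table."""

    X: np.ndarray                 # (n_obs, n_cols) float64
    colnames: list[str]
    cluster_index: np.ndarray     # (n_obs,) int — row -> person position
    person_ids: list              # unique person ids, in order of cluster_index
    spec: ModelSpec

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)


def _main_dummies(table: pd.DataFrame, term: Term) -> dict[str, np.ndarray]:
    col = table[term.name]
    seen = set(col.unique().tolist())
    unknown = seen - set(term.levels)
    if unknown:
        raise DataValidationError(
            f"column {term.name!r} contains levels {sorted(map(str, unknown))} "
            f"not declared in the model spec"
        )
    return {
        f"{term.name}={lv}": (col == lv).to_numpy(dtype=np.float64)
        for lv in term.levels[1:]
    }


def _encode(table: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Dummy-code ``table`` per ``spec`` without any rank check."""
    dummies: dict[str, np.ndarray] = {
        "intercept": np.ones(len(table), dtype=np.float64)
    }
    for t in spec.fixed_terms:
        dummies.update(_main_dummies(table, t))
    for a, b in spec.interactions:
        ta, tb = spec.term(a), spec.term(b)
        for la in ta.levels[1:]:
            for lb in tb.levels[1:]:
                dummies[f"{a}={la}:{b}={lb}"] = (
                    dummies[f"{a}={la}"] * dummies[f"{b}={lb}"]
                )
    cols = spec.column_names()
    X = np.column_stack([dummies[c] for c in cols]) if len(table) else np.zeros((0, len(cols)))
    return X, cols


def build_design(table: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Build the dummy-coded design matrix from an analysis table.

    The table needs one row per visit observation with the spec's covariate
    columns plus ``person_id``. Raises :class:`RankDeficiencyError` naming the
    aliased columns if the design is not full column rank.
    """
    required = {"person_id"} | {t.name for t in spec.fixed_terms}
    missing = required - set(table.columns)
    if missing:
        raise DataValidationError(f"analysis table lacks columns {sorted(missing)}")
    X, cols = _encode(table, spec)
    if len(table) and len(table) >= len(cols):
        R = np.linalg.qr(X, mode="r")
        diag = np.abs(np.diag(R))
        tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
        bad = diag <= tol
        if bad.any():
            raise RankDeficiencyError([cols[i] for i in np.flatnonzero(bad)])
    pid = table["person_id"].to_numpy()
    person_ids, cluster = np.unique(pid, return_inverse=True)
    return DesignMatrix(
        X=X,
        colnames=cols,
        cluster_index=cluster.astype(np.int64),
        person_ids=person_ids.tolist(),
        spec=spec,
    )


def design_row(profile: dict, spec: ModelSpec) -> np.ndarray:
    """Encode one covariate profile as a single design row (no rank check)."""
    table = pd.DataFrame([profile])
    for t in spec.fixed_terms:
        if t.name not in table.columns:
            raise ConfigurationError(f"profile lacks covariate {t.name!r}")
        if table[t.name].iloc[0] not in t.levels:
            raise ConfigurationError(
                f"profile level {table[t.name].iloc[0]!r} unknown for {t.name!r}"
            )
    X, _ = _encode(table, spec)
    return X[0]


@dataclass
class PosteriorSample:
    """Joint posterior draws of the random-intercept logistic model."""

    beta: np.ndarray              # (S, P)
    colnames: list[str]
    sigma_u: np.ndarray           # (S,)
    u: np.ndarray | None          # (S, n_persons) or None if not stored
    pointwise_loglik: np.ndarray  # (S, n_obs)
    chain_ids: np.ndarray         # (S,)
    person_ids: list
    spec: ModelSpec
    seed: int
    diagnostics: "Diagnostics | None" = None

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain_ids.max()) + 1 if self.chain_ids.size else 0

    def beta_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.beta, columns=self.colnames)
        df["sigma_u"] = self.sigma_u
        df["chain"] = self.chain_ids
        return df

    def save(self, draws_csv, sidecar_json) -> None:
        """Persist draws as columnar CSV plus a JSON sidecar with metadata."""
        import json

        self.beta_frame().to_csv(draws_csv, index=False)
        meta = {
            "seed": self.seed,
            "n_draws": int(self.n_draws),
            "n_chains": int(self.n_chains),
            "colnames": self.colnames,
            "interactions": [list(p) for p in self.spec.interactions],
            "coef_prior_scale": self.spec.coef_prior_scale,
            "re_sd_prior": self.spec.re_sd_prior,
            "converged": None if self.diagnostics is None else bool(self.diagnostics.converged),
            "max_rhat": None if self.diagnostics is None else self.diagnostics.max_rhat,
            "min_ess": None if self.diagnostics is None else self.diagnostics.min_ess,
        }
        with open(sidecar_json, "w") as fh:
            json.dump(meta, fh, indent=2)


def _slice_sigma(sigma: float, n: int, ssq: float, prior_scale: float,
                 rng: np.random.Generator, width: float = 0.5,
                 max_steps: int = 50) -> float:
    """Stepping-out slice update of sigma_u given the person intercepts."""

    def logf(s: float) -> float:
        if s <= 0.0:
            return -np.inf
        out = -s * s / (2.0 * prior_scale * prior_scale)
        if n:
            out += -n * math.log(s) - ssq / (2.0 * s * s)
        return out

    y = logf(sigma) - rng.exponential()
    lo = sigma - width * rng.random()
    hi = lo + width
    steps = max_steps
    while lo > 0.0 and logf(lo) > y and steps > 0:
        lo -= width
        steps -= 1
    lo = max(lo, 0.0)
    steps = max_steps
    while logf(hi) > y and steps > 0:
        hi += width
        steps -= 1
    while True:
        prop = lo + (hi - lo) * rng.random()
        if logf(prop) > y:
            return prop
        if prop < sigma:
            lo = prop
        else:
            hi = prop


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def _norm_ppf(q: float) -> float:
    from scipy.special import ndtri

    return float(ndtri(q))


def _bernoulli_loglik(eta: np.ndarray, sign: np.ndarray) -> np.ndarray:
    # log p(y | eta) = -log(1 + exp(-(2y-1) eta)), stable at large |eta|
    return -np.logaddexp(0.0, -sign * eta)


def fit_posterior(
    design: DesignMatrix,
    y: np.ndarray,
    spec: ModelSpec | None = None,
    n_chains: int = 4,
    n_iter: int = 2500,
    n_warmup: int = 1000,
    seed: int | None = None,
    random_intercept: bool = True,
    store_u: bool = True,
) -> PosteriorSample:
    """Draw from the joint posterior of (beta, sigma_u, u) by PG-Gibbs.

    ``n_iter`` counts total sweeps per chain; the first ``n_warmup`` are
    discarded. With ``random_intercept=False`` the random effect is pinned to
    zero (plain Bayesian logistic regression). The conditional pointwise
    log-likelihood log p(y_j | beta_s, u_s) is stored for every kept draw.
    """
    if spec is None:
        spec = design.spec
    if seed is None:
        raise ConfigurationError("fit_posterior requires an explicit seed")
    if n_warmup >= n_iter:
        raise ConfigurationError("n_warmup must be < n_iter")
    X = np.ascontiguousarray(design.X, dtype=np.float64)
    if X.size and not np.isfinite(X).all():
        raise DataValidationError("design matrix contains non-finite values")
    y = np.asarray(y)
    if y.shape != (design.n_obs,):
        raise DataValidationError("y length does not match design rows")
    if y.size and not np.isin(y, (0, 1)).all():
        raise DataValidationError("y must be binary (0/1)")
    y = y.astype(np.float64)

    n, P = X.shape
    n_persons = design.n_persons
    cluster = design.cluster_index
    kappa = y - 0.5
    sign = 2.0 * y - 1.0
    prior_prec = np.eye(P) / spec.coef_prior_scale**2

    n_keep = n_iter - n_warmup
    S = n_keep * n_chains
    beta_out = np.empty((S, P))
    sigma_out = np.empty(S)
    u_out = np.empty((S, n_persons)) if (store_u and random_intercept) else None
    loglik_out = np.empty((S, n))
    chain_ids = np.empty(S, dtype=np.int64)

    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(2 * n_chains)

    omega = np.empty(n)
    for c in range(n_chains):
        seed_pg(int(states[2 * c]))
        rng = np.random.default_rng(int(states[2 * c + 1]))
        beta = np.zeros(P)
        u = np.zeros(n_persons)
        sigma = spec.re_sd_prior if random_intercept else 0.0
        kappa_by_person = (
            np.bincount(cluster, weights=kappa, minlength=n_persons) if n else None
        )
        for it in range(n_iter):
            eta = X @ beta + (u[cluster] if random_intercept and n else 0.0)
            if n:
                pg_draw(eta, omega)
                XtO = X.T * omega
                prec = XtO @ X + prior_prec
                rhs = X.T @ kappa
                if random_intercept:
                    # collapse u out of the beta update (Woodbury per person):
                    # the marginal precision of beta subtracts, per person i,
                    # c_i a_i a_i' with a_i = sum_j omega_j x_j and
                    # c_i = sigma^2 / (1 + sigma^2 sum_j omega_j)
                    s0 = np.bincount(cluster, weights=omega, minlength=n_persons)
                    A = np.stack(
                        [
                            np.bincount(cluster, weights=XtO[p], minlength=n_persons)
                            for p in range(P)
                        ],
                        axis=1,
                    )
                    shrink = sigma**2 / (1.0 + sigma**2 * s0)
                    prec = prec - (A * shrink[:, None]).T @ A
                    rhs = rhs - A.T @ (shrink * kappa_by_person)
                cf = cho_factor(prec, lower=True)
                m = cho_solve(cf, rhs)
                z = rng.standard_normal(P)
                beta = m + solve_triangular(cf[0].T, z, lower=False)
            else:
                beta = rng.normal(0.0, spec.coef_prior_scale, size=P)
            if random_intercept:
                if n:
                    xb = X @ beta
                    s1 = np.bincount(
                        cluster, weights=kappa - omega * xb, minlength=n_persons
                    )
                else:
                    s0 = np.zeros(n_persons)
                    s1 = np.zeros(n_persons)
                prec_u = s0 + 1.0 / sigma**2
                u = s1 / prec_u + rng.standard_normal(n_persons) / np.sqrt(prec_u)
                sigma = _slice_sigma(
                    sigma, n_persons, float(u @ u), spec.re_sd_prior, rng
                )
                if n:
                    # interweaving (ASIS): re-draw sigma in the non-centered
                    # parametrization u = sigma * v, where its full
                    # conditional under PG augmentation is an exact
                    # zero-truncated Normal; breaks the sigma-u coupling
                    v = u / sigma
                    v_rows = v[cluster]
                    prec_s = float((omega * v_rows**2).sum()) + 1.0 / spec.re_sd_prior**2
                    mean_s = float((v_rows * (kappa - omega * xb)).sum()) / prec_s
                    sd_s = 1.0 / math.sqrt(prec_s)
                    lo = _norm_cdf(-mean_s / sd_s)
                    quant = lo + (1.0 - lo) * rng.random()
                    sigma = mean_s + sd_s * _norm_ppf(min(quant, 1.0 - 1e-16))
                    sigma = max(sigma, 1e-12)
                    u = sigma * v
            if it >= n_warmup:
                k = c * n_keep + (it - n_warmup)
                beta_out[k] = beta
                sigma_out[k] = sigma
                if u_out is not None:
                    u_out[k] = u
                eta = X @ beta + (u[cluster] if random_intercept and n else 0.0)
                loglik_out[k] = _bernoulli_loglik(eta, sign)
                chain_ids[k] = c

    return PosteriorSample(
        beta=beta_out,
        colnames=list(design.colnames),
        sigma_u=sigma_out,
        u=u_out,
        pointwise_loglik=loglik_out,
        chain_ids=chain_ids,
        person_ids=list(design.person_ids),
        spec=spec,
        seed=seed,
    )


@dataclass
class Diagnostics:
    """Split-R-hat / effective-sample-size summary of a posterior sample."""

    table: pd.DataFrame           # index: parameter; columns: rhat, ess
    converged: bool
    max_rhat: float
    min_ess: float
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0


def diagnose(
    sample: PosteriorSample,
    rhat_threshold: float = 1.01,
    ess_threshold: float = 400.0,
    include_random_intercept_sd: bool = True,
) -> Diagnostics:
    """Per-parameter split-R-hat and bulk ESS (via arviz) for the fixed
    effects and, when sampled, sigma_u. Convergence is declared iff
    max R-hat < ``rhat_threshold`` and min ESS > ``ess_threshold``.
    """
    import arviz as az

    C = sample.n_chains
    if C < 2:
        warnings.warn("split-R-hat needs >= 2 chains; diagnostics unavailable")
        tab = pd.DataFrame(
            index=pd.Index(sample.colnames, name="parameter"),
            columns=["rhat", "ess"],
            dtype=float,
        )
        return Diagnostics(tab, False, float("nan"), float("nan"),
                           rhat_threshold, ess_threshold)
    D = sample.n_draws // C
    data = {
        name: sample.beta[:, i].reshape(C, D)
        for i, name in enumerate(sample.colnames)
    }
    if include_random_intercept_sd and sample.sigma_u.std() > 0:
        data["sigma_u"] = sample.sigma_u.reshape(C, D)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior={k: v for k, v in data.items()})
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    tab = pd.DataFrame(
        {
            "rhat": {k: float(rhat[k].values) for k in data},
            "ess": {k: float(ess[k].values) for k in data},
        }
    )
    tab.index.name = "parameter"
    max_rhat = float(tab["rhat"].max())
    min_ess = float(tab["ess"].min())
    converged = bool(max_rhat < rhat_threshold and min_ess > ess_threshold)
    return Diagnostics(tab, converged, max_rhat, min_ess,
                       rhat_threshold, ess_threshold)
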