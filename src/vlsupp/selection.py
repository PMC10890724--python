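"""Two-step interaction selection by expected log pointwise density (ELPD).

The ELPD of a fitted model is estimated in WAIC form from the conditional
pointwise log-likelihood matrix (draws x observations):

    lpd_j       = log mean_s exp(loglik[s, j])
    p_j         = var_s(loglik[s, j])          (effective-parameter penalty)
    pointwise_j = lpd_j - p_j
    elpd        = sum_j pointwise_j,  se = sqrt(n * var_j(pointwise_j))

Model comparison uses the paired pointwise differences, and a candidate
interaction is "eligible" iff its ELPD gain over the no-interaction base
model strictly exceeds twice the standard error of the difference. The
final model is the best-ELPD subset of the eligible interactions (ties go
to the model with fewer interaction terms).
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from vlsupp.errors import ConfigurationError, ConvergenceError, DataValidationError
from vlsupp.model import ModelSpec, PosteriorSample, build_design, diagnose, fit_posterior

__all__ = [
    "ElpdResult",
    "ModelComparison",
    "SelectionResult",
    "compute_elpd",
    "compare",
    "select_final_model",
    "all_candidate_pairs",
]


@dataclass
class ElpdResult:
    elpd: float
    pointwise: np.ndarray
    se: float
    n_obs: int


@dataclass
class ModelComparison:
    model_a: str
    model_b: str
    delta_elpd: float
    se_delta: float
    eligible: bool


@dataclass
class SelectionResult:
    chosen: ModelSpec
    step1: list[ModelComparison]
    eligible: list[tuple[str, str]]
    subset_elpds: dict[str, float]
    base_elpd: float
    samples: dict = field(default_factory=dict)  # subset key -> (beta df, sigma)


def compute_elpd(sample: PosteriorSample) -> ElpdResult:
    """WAIC-form ELPD from a posterior sample's pointwise log-likelihood."""
    ll = sample.pointwise_loglik
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise DataValidationError("need a (draws >= 2) x (obs) log-likelihood matrix")
    S, n = ll.shape
    lpd = logsumexp(ll, axis=0) - np.log(S)
    if not np.isfinite(lpd).all():
        bad = np.flatnonzero(~np.isfinite(lpd))[:5]
        raise DataValidationError(
            f"degenerate pointwise likelihood (non-finite lpd) at observations {bad.tolist()}"
        )
    p = ll.var(axis=0, ddof=1)
    pointwise = lpd - p
    elpd = float(pointwise.sum())
    se = float(np.sqrt(n * pointwise.var(ddof=1))) if n > 1 else 0.0
    return ElpdResult(elpd=elpd, pointwise=pointwise, se=se, n_obs=n)


def compare(base: ElpdResult, alt: ElpdResult,
            name_base: str = "base", name_alt: str = "alt") -> ModelComparison:
    """Paired ELPD difference (alt - base) with the 2-SE eligibility rule."""
    if base.n_obs != alt.n_obs:
        raise DataValidationError(
            f"cannot compare models fit to different data ({base.n_obs} vs {alt.n_obs} obs)"
        )
    diff = alt.pointwise - base.pointwise
    delta = float(diff.sum())
    se = float(np.sqrt(base.n_obs * diff.var(ddof=1))) if base.n_obs > 1 else 0.0
    return ModelComparison(
        model_a=name_base,
        model_b=name_alt,
        delta_elpd=delta,
        se_delta=se,
        eligible=bool(delta > 2.0 * se),
    )


def all_candidate_pairs(spec: ModelSpec) -> list[tuple[str, str]]:
    """All unordered pairs of the spec's fixed terms (10 for 5 covariates)."""
    names = [t.name for t in spec.fixed_terms]
    return list(itertools.combinations(names, 2))


def _subset_key(subset) -> str:
    return " + ".join(f"{a}:{b}" for a, b in subset) if subset else "(none)"


def _fit_seed(seed: int, subset) -> int:
    # deterministic per-subset seed, independent of candidate ordering
    return (seed * 1000003 + zlib.crc32(_subset_key(subset).encode())) % (2**31)


def select_final_model(
    table,
    base_spec: ModelSpec,
    candidates: list[tuple[str, str]] | None = None,
    seed: int = 0,
    n_chains: int = 2,
    n_iter: int = 1200,
    n_warmup: int = 400,
    check_convergence: bool = True,
    keep_draws: bool = False,
) -> SelectionResult:
    """Two-step search over two-way interactions.

    Step 1 fits the base model and the base plus each single candidate
    interaction and marks as eligible every candidate whose ELPD gain
    strictly exceeds twice its standard error. Step 2 fits every subset of
    the eligible interactions (the empty subset is the base model) and
    returns the specification with the highest ELPD, breaking exact ties
    toward fewer interaction terms. Candidate order does not affect the
    result. A non-convergent fit aborts the selection.
    """
    if candidates is None:
        candidates = all_candidate_pairs(base_spec)
    # canonical order: by fixed-term position, so seeds/outcomes are
    # invariant to the caller's candidate ordering
    names = [t.name for t in base_spec.fixed_terms]
    canon = []
    for a, b in candidates:
        if a not in names or b not in names:
            raise ConfigurationError(f"candidate {(a, b)!r} is not a pair of fixed terms")
        if names.index(a) > names.index(b):
            a, b = b, a
        if (a, b) not in canon:
            canon.append((a, b))
    canon.sort(key=lambda p: (names.index(p[0]), names.index(p[1])))

    cache: dict[tuple, ElpdResult] = {}
    kept_draws: dict = {}

    def fit_subset(subset: tuple) -> ElpdResult:
        subset = tuple(subset)
        if subset not in cache:
            spec = base_spec.with_interactions(
                tuple(base_spec.interactions) + subset
            )
            design = build_design(table, spec)
            sample = fit_posterior(
                design,
                table["suppressed"].to_numpy(),
                spec,
                n_chains=n_chains,
                n_iter=n_iter,
                n_warmup=n_warmup,
                seed=_fit_seed(seed, subset),
                store_u=False,
            )
            if check_convergence:
                diag = diagnose(sample)
                if not diag.converged:
                    raise ConvergenceError(
                        f"fit for interactions {_subset_key(subset)} did not "
                        f"converge (max R-hat {diag.max_rhat:.4f}, "
                        f"min ESS {diag.min_ess:.0f})"
                    )
            cache[subset] = compute_elpd(sample)
            if keep_draws:
                kept_draws[_subset_key(subset)] = (
                    sample.beta.copy(),
                    list(sample.colnames),
                    sample.sigma_u.copy(),
                )
        return cache[subset]

    base_elpd = fit_subset(())
    step1 = []
    eligible = []
    for pair in canon:
        res = fit_subset((pair,))
        cmpres = compare(base_elpd, res, "(none)", _subset_key((pair,)))
        step1.append(cmpres)
        if cmpres.eligible:
            eligible.append(pair)

    subset_elpds: dict[str, float] = {}
    best_subset: tuple = ()
    best = (base_elpd.elpd, 0)
    subset_elpds["(none)"] = base_elpd.elpd
    for r in range(1, len(eligible) + 1):
        for combo in itertools.combinations(eligible, r):
            res = fit_subset(combo)
            subset_elpds[_subset_key(combo)] = res.elpd
            if res.elpd > best[0] or (res.elpd == best[0] and r < best[1]):
                best = (res.elpd, r)
                best_subset = combo

    chosen = base_spec.with_interactions(
        tuple(base_spec.interactions) + tuple(best_subset)
    )
    return SelectionResult(
        chosen=chosen,
        step1=step1,
        eligible=eligible,
        subset_elpds=subset_elpds,
        base_elpd=base_elpd.elpd,
        samples=kept_draws,
    )
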