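"""Configured, seeded pipeline: simulate -> prepare -> fit -> select ->
estimate -> report, with every intermediate persisted as plain CSV/JSON and
a manifest (config hash, seed, versions, stage timings, output hashes)."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import List, Optional, Tuple

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

import vlsupp
from vlsupp.effects import (
    CovariateProfile,
    crude_proportions_table,
    estimates_to_frame,
    marginal_aor,
    nonstandardized_predictions,
    standardized_predictions,
)
from vlsupp.errors import ConfigurationError
from vlsupp.model import DEFAULT_TERMS, ModelSpec, build_design, diagnose, fit_posterior
from vlsupp.prep import build_analysis_table
from vlsupp.report import report_descriptives, report_estimates
from vlsupp.selection import select_final_model
from vlsupp.simulate import SimulationConfig, generate_cohort, generate_outcomes, write_dataset

log = logging.getLogger("vlsupp")


class SamplerSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chains: int = 4
    iters: int = 2500
    warmup: int = 1000


class SelectionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    candidates: Optional[List[Tuple[str, str]]] = None
    chains: int = 2
    iters: int = 1200
    warmup: int = 400
    check_convergence: bool = True


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    simulation: Optional[SimulationConfig] = Field(default_factory=SimulationConfig)
    persons_csv: Optional[str] = None
    viral_loads_csv: Optional[str] = None
    weeks: Tuple[int, ...] = (12, 24, 48, 72, 96)
    half_width_days: int = 28
    coef_prior_scale: float = 2.5
    re_sd_prior: float = 1.0
    sampler: SamplerSettings = Field(default_factory=SamplerSettings)
    selection: SelectionSettings = Field(default_factory=SelectionSettings)
    complete_case: bool = False
    figures: bool = True
    out_dir: str = "vlsupp_run"
    seed: Optional[int] = None


def load_posterior(run_dir) -> "vlsupp.model.PosteriorSample":
    """Rebuild a (beta, sigma_u)-only posterior sample from persisted CSV +
    JSON sidecar, sufficient for the marginal-effects machinery."""
    import numpy as np

    from vlsupp.model import PosteriorSample

    run_dir = Path(run_dir)
    draws = pd.read_csv(run_dir / "posterior_draws.csv")
    meta = json.loads((run_dir / "posterior_meta.json").read_text())
    colnames = meta["colnames"]
    spec = ModelSpec(
        fixed_terms=DEFAULT_TERMS,
        interactions=tuple(tuple(p) for p in meta["interactions"]),
        coef_prior_scale=meta["coef_prior_scale"],
        re_sd_prior=meta["re_sd_prior"],
    )
    S = len(draws)
    return PosteriorSample(
        beta=draws[colnames].to_numpy(),
        colnames=colnames,
        sigma_u=draws["sigma_u"].to_numpy(),
        u=None,
        pointwise_loglik=np.zeros((S, 0)),
        chain_ids=draws["chain"].to_numpy(),
        person_ids=[],
        spec=spec,
        seed=meta["seed"],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _base_spec(config: RunConfig) -> ModelSpec:
    return ModelSpec(
        fixed_terms=DEFAULT_TERMS,
        interactions=(),
        coef_prior_scale=config.coef_prior_scale,
        re_sd_prior=config.re_sd_prior,
    )


def _regimen_week_aors(sample, weeks, reference_profile) -> list:
    """Regimen contrasts stratified by week, at the reference covariates."""
    contrasts = [("DTG", "EFV"), ("ATVr", "EFV"), ("DTG", "ATVr")]
    out = []
    for week in weeks:
        for a, b in contrasts:
            pa = CovariateProfile(regimen=a, week=week, **reference_profile)
            pb = CovariateProfile(regimen=b, week=week, **reference_profile)
            out.append(marginal_aor(sample, pa, pb))
    return out


def _covariate_aors(sample, spec: ModelSpec, reference_profile) -> list:
    """Non-regimen effects vs their reference level, at the model reference
    point (EFV, week 12)."""
    out = []
    base = dict(regimen="EFV", week=12, **reference_profile)
    for term_name in ("sex", "age_group", "cd4_group"):
        term = spec.term(term_name)
        for level in term.levels[1:]:
            alt = dict(base)
            alt[term_name] = level
            out.append(
                marginal_aor(
                    sample, CovariateProfile(**alt), CovariateProfile(**base)
                )
            )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dictionary.

    Re-running with an identical config (and seed) reproduces identical
    tables. Any stage failure raises with the stage named.
    """
    if config.seed is None:
        raise ConfigurationError("run_pipeline requires a seed (no silent default)")
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)

    config_json = config.model_dump_json(indent=2)
    (outdir / "run_config.json").write_text(config_json)
    manifest: dict = {
        "package_version": vlsupp.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "stages": {},
        "outputs": {},
    }
    timings = manifest["stages"]

    stage = "simulate/load"
    try:
        t0 = time.perf_counter()
        if config.persons_csv is not None:
            persons = pd.read_csv(config.persons_csv, dtype={"person_id": str})
            vl = pd.read_csv(config.viral_loads_csv, dtype={"person_id": str})
            log.info("loaded %d persons, %d viral loads", len(persons), len(vl))
        else:
            sim = config.simulation.model_copy(update={"seed": config.seed})
            persons = generate_cohort(sim)
            vl = generate_outcomes(persons, sim)
            write_dataset(persons, vl, outdir)
            log.info("simulated %d persons, %d viral loads", len(persons), len(vl))
        timings[stage] = time.perf_counter() - t0

        stage = "prepare"
        t0 = time.perf_counter()
        table, prep_report = build_analysis_table(
            persons,
            vl,
            complete_case=config.complete_case,
            weeks=tuple(config.weeks),
            half_width_days=config.half_width_days,
        )
        table.to_csv(outdir / "analysis_table.csv", index=False)
        (outdir / "prep_report.json").write_text(
            json.dumps(
                {
                    "n_input_persons": prep_report.inclusion.n_input,
                    "n_excluded_age": prep_report.inclusion.n_excluded_age,
                    "n_excluded_followup": prep_report.inclusion.n_excluded_followup,
                    "n_included_persons": prep_report.inclusion.n_included,
                    "n_measurements": prep_report.n_measurements,
                    "n_assigned": prep_report.n_assigned,
                    "n_unassigned": prep_report.n_unassigned,
                    "n_observed_rows": prep_report.n_observed_rows,
                    "n_imputed_rows": prep_report.n_imputed_rows,
                    "complete_case": prep_report.complete_case,
                },
                indent=2,
            )
        )
        log.info(
            "analysis table: %d rows (%d observed, %d imputed)",
            len(table), prep_report.n_observed_rows, prep_report.n_imputed_rows,
        )
        timings[stage] = time.perf_counter() - t0

        stage = "select"
        t0 = time.perf_counter()
        base_spec = _base_spec(config)
        if config.selection.enabled:
            sel = select_final_model(
                table,
                base_spec,
                candidates=config.selection.candidates,
                seed=config.seed,
                n_chains=config.selection.chains,
                n_iter=config.selection.iters,
                n_warmup=config.selection.warmup,
                check_convergence=config.selection.check_convergence,
            )
            chosen_spec = sel.chosen
            (outdir / "selection_report.json").write_text(
                json.dumps(
                    {
                        "base_elpd": sel.base_elpd,
                        "step1": [
                            {
                                "candidate": c.model_b,
                                "delta_elpd": c.delta_elpd,
                                "se_delta": c.se_delta,
                                "eligible": c.eligible,
                            }
                            for c in sel.step1
                        ],
                        "eligible": [list(p) for p in sel.eligible],
                        "subset_elpds": sel.subset_elpds,
                        "chosen_interactions": [list(p) for p in chosen_spec.interactions],
                    },
                    indent=2,
                )
            )
            log.info("selected interactions: %s", list(chosen_spec.interactions))
        else:
            chosen_spec = base_spec.with_interactions((("regimen", "week"),))
            log.info("selection disabled; using regimen-by-week interaction")
        timings[stage] = time.perf_counter() - t0

        stage = "fit"
        t0 = time.perf_counter()
        design = build_design(table, chosen_spec)
        sample = fit_posterior(
            design,
            table["suppressed"].to_numpy(),
            chosen_spec,
            n_chains=config.sampler.chains,
            n_iter=config.sampler.iters,
            n_warmup=config.sampler.warmup,
            seed=config.seed,
            store_u=False,
        )
        sample.diagnostics = diagnose(sample)
        if not sample.diagnostics.converged:
            log.warning(
                "final fit convergence flagged: max R-hat %.4f, min ESS %.0f",
                sample.diagnostics.max_rhat, sample.diagnostics.min_ess,
            )
        sample.save(outdir / "posterior_draws.csv", outdir / "posterior_meta.json")
        timings[stage] = time.perf_counter() - t0

        stage = "estimate"
        t0 = time.perf_counter()
        reference_profile = dict(sex="female", age_group="12-19", cd4_group="<200")
        estimates = (
            crude_proportions_table(table)
            + _regimen_week_aors(sample, config.weeks, reference_profile)
            + _covariate_aors(sample, chosen_spec, reference_profile)
            + standardized_predictions(sample, table, weeks=config.weeks)
            + nonstandardized_predictions(sample, table)
        )
        est_frame = estimates_to_frame(estimates)
        est_frame.to_csv(outdir / "estimates.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "report"
        t0 = time.perf_counter()
        descriptives = report_descriptives(persons, table)
        descriptives.to_csv(outdir / "descriptives.csv")
        report_estimates(est_frame, outdir / "report", figures=config.figures)
        timings[stage] = time.perf_counter() - t0
    except Exception:
        log.exception("pipeline failed in stage %r", stage)
        log.removeHandler(fh)
        fh.close()
        raise

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json" and path.name != "run.log":
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.removeHandler(fh)
    fh.close()
    return manifest
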