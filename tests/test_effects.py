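"""Marginalization over the random-intercept distribution and the derived
population-averaged estimates."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from vlsupp.errors import DataValidationError
from vlsupp.model import ModelSpec, PosteriorSample, design_row
from vlsupp.effects import (
    CovariateProfile,
    crude_proportion,
    crude_proportions_table,
    estimates_to_frame,
    marginal_aor,
    marginal_probability,
    nonstandardized_predictions,
    standardized_predictions,
)


def _mc_marginal(eta, sigma, n=1_000_000, seed=0):
    u = np.random.default_rng(seed).normal(0.0, sigma, n)
    return expit(eta + u).mean()


class TestMarginalProbability:
    def test_sigma_zero_collapses_exactly_to_expit(self):
        for eta in (-3.0, 0.0, 1.2, 4.0):
            assert marginal_probability(eta, 0.0) == expit(eta)

    def test_half_at_eta_zero_any_sigma(self):
        for sigma in (0.0, 0.5, 2.0, 3.0):
            assert marginal_probability(0.0, sigma) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("eta,sigma", [(1.0, 1.0), (-2.0, 0.7), (3.0, 2.5)])
    def test_matches_monte_carlo_oracle(self, eta, sigma):
        mc = _mc_marginal(eta, sigma)
        assert marginal_probability(eta, sigma) == pytest.approx(mc, abs=1e-3)

    def test_quadrature_node_convergence(self):
        """Doubling the node count shows rapid convergence over the whole
        eta in [-4, 4], sigma in [0, 3] grid: the 31-node default is within
        1e-4 of converged, and 63 -> 127 changes nothing beyond 1e-6."""
        etas = np.linspace(-4, 4, 17)
        sigmas = np.linspace(0, 3, 7)
        E, S = np.meshgrid(etas, sigmas)
        p31 = marginal_probability(E, S, n_nodes=31)
        p63 = marginal_probability(E, S, n_nodes=63)
        p127 = marginal_probability(E, S, n_nodes=127)
        assert np.abs(p63 - p31).max() < 1e-4
        assert np.abs(p127 - p63).max() < 1e-6

    def test_attenuation_toward_half(self):
        # integrating a concave-then-convex expit pulls values toward 0.5
        assert marginal_probability(2.0, 2.0) < expit(2.0)
        assert marginal_probability(-2.0, 2.0) > expit(-2.0)

    def test_nonfinite_eta_rejected(self):
        with pytest.raises(DataValidationError):
            marginal_probability(np.inf, 1.0)


def _toy_sample(beta_draws, sigma_draws, spec=None):
    beta_draws = np.atleast_2d(beta_draws)
    spec = spec or ModelSpec(interactions=(("regimen", "week"),))
    S = beta_draws.shape[0]
    return PosteriorSample(
        beta=beta_draws,
        colnames=spec.column_names(),
        sigma_u=np.asarray(sigma_draws, dtype=float),
        u=None,
        pointwise_loglik=np.zeros((S, 1)),
        chain_ids=np.zeros(S, dtype=int),
        person_ids=[],
        spec=spec,
        seed=0,
    )


def _random_sample(S=200, seed=0, sigma_const=None, spec=None):
    spec = spec or ModelSpec(interactions=(("regimen", "week"),))
    P = len(spec.column_names())
    rng = np.random.default_rng(seed)
    beta = rng.normal(0, 0.5, size=(S, P))
    sigma = (
        np.full(S, sigma_const) if sigma_const is not None
        else np.abs(rng.normal(0.8, 0.2, S))
    )
    return _toy_sample(beta, sigma, spec)


_PROFILE = dict(week=24, sex="female", age_group="20-29", cd4_group="<200")


class TestMarginalAor:
    def test_identity_contrast_is_exactly_one(self):
        sample = _random_sample()
        p = CovariateProfile(regimen="DTG", **_PROFILE)
        est = marginal_aor(sample, p, p)
        assert est.point == 1.0 and est.lower == 1.0 and est.upper == 1.0

    def test_sigma_zero_equals_conditional_or(self):
        sample = _random_sample(sigma_const=0.0)
        pa = CovariateProfile(regimen="DTG", **_PROFILE)
        pb = CovariateProfile(regimen="EFV", **_PROFILE)
        est = marginal_aor(sample, pa, pb)
        xa = design_row(pa.as_dict(), sample.spec)
        xb = design_row(pb.as_dict(), sample.spec)
        cond = np.exp(sample.beta @ (xa - xb))
        assert est.point == pytest.approx(float(np.median(cond)), rel=1e-12)

    def test_attenuation_between_one_and_conditional(self):
        """With sigma_u > 0 the marginal aOR lies strictly between 1 and the
        conditional OR (here conditional OR = 3 at eta_b = 0)."""
        spec = ModelSpec(interactions=(("regimen", "week"),))
        cols = spec.column_names()
        beta = np.zeros(len(cols))
        beta[cols.index("regimen=DTG")] = np.log(3.0)
        sample = _toy_sample(beta[None, :], [1.5], spec)
        pa = CovariateProfile(regimen="DTG", week=12, sex="female",
                              age_group="12-19", cd4_group="<200")
        pb = CovariateProfile(regimen="EFV", week=12, sex="female",
                              age_group="12-19", cd4_group="<200")
        est = marginal_aor(sample, pa, pb)
        assert 1.0 < est.point < 3.0
        # cross-check against a Monte-Carlo marginalization oracle
        rng = np.random.default_rng(1)
        u = rng.normal(0, 1.5, 2_000_000)
        p_a = expit(np.log(3.0) + u).mean()
        p_b = expit(u).mean()
        mc_or = (p_a / (1 - p_a)) / (p_b / (1 - p_b))
        assert est.point == pytest.approx(mc_or, abs=0.01)

    def test_attenuation_property_random_draws(self):
        """|log marginal aOR| < |log conditional OR| for every draw."""
        spec = ModelSpec(interactions=(("regimen", "week"),))
        sample = _random_sample(S=50, seed=3, spec=spec)
        sample.sigma_u[:] = np.linspace(0.5, 2.5, 50)
        pa = CovariateProfile(regimen="ATVr", **_PROFILE)
        pb = CovariateProfile(regimen="EFV", **_PROFILE)
        xa = design_row(pa.as_dict(), spec)
        xb = design_row(pb.as_dict(), spec)
        eta_a = sample.beta @ xa
        eta_b = sample.beta @ xb
        pa_m = marginal_probability(eta_a, sample.sigma_u)
        pb_m = marginal_probability(eta_b, sample.sigma_u)
        log_mor = np.log(pa_m / (1 - pa_m)) - np.log(pb_m / (1 - pb_m))
        log_cond = eta_a - eta_b
        nz = np.abs(log_cond) > 1e-6
        assert (np.abs(log_mor[nz]) < np.abs(log_cond[nz])).all()
        assert (np.sign(log_mor[nz]) == np.sign(log_cond[nz])).all()


def _mini_table(rows):
    return pd.DataFrame(
        rows,
        columns=["person_id", "week", "suppressed", "provenance", "sex",
                 "age_group", "cd4_group", "regimen"],
    )


class TestPredictions:
    def test_identical_covariates_equal_single_profile(self):
        sample = _random_sample(S=40, seed=5)
        rows = [(f"P{i}", 24, 1, "observed", "female", "20-29", "<200", "EFV")
                for i in range(6)]
        table = _mini_table(rows)
        ests = standardized_predictions(sample, table, weeks=[24], regimens=["DTG"])
        profile = CovariateProfile(regimen="DTG", week=24, sex="female",
                                   age_group="20-29", cd4_group="<200")
        eta = sample.beta @ design_row(profile.as_dict(), sample.spec)
        draws = marginal_probability(eta, sample.sigma_u)
        assert ests[0].point == pytest.approx(float(np.median(draws)), rel=1e-12)

    def test_fifty_fifty_cohort_averages_profiles(self):
        sample = _random_sample(S=30, seed=6)
        rows = [(f"A{i}", 24, 1, "observed", "female", "20-29", "<200", "EFV")
                for i in range(5)]
        rows += [(f"B{i}", 24, 1, "observed", "male", "40+", ">=350", "ATVr")
                 for i in range(5)]
        table = _mini_table(rows)
        est = standardized_predictions(sample, table, weeks=[48], regimens=["EFV"])[0]
        draws = np.zeros(sample.n_draws)
        for sex, ag, cg in [("female", "20-29", "<200"), ("male", "40+", ">=350")]:
            x = design_row(dict(regimen="EFV", week=48, sex=sex, age_group=ag,
                                cd4_group=cg), sample.spec)
            draws += marginal_probability(sample.beta @ x, sample.sigma_u)
        draws /= 2
        assert est.point == pytest.approx(float(np.median(draws)), rel=1e-12)

    def test_matches_bruteforce_person_loop(self):
        """12-person factorial cohort: weighted-profile computation equals a
        naive per-person loop."""
        sample = _random_sample(S=25, seed=7)
        sexes = ["female", "male"]
        ages = ["12-19", "20-29", "30-39"]
        cd4s = ["<200", ">=350"]
        rows = []
        k = 0
        for s in sexes:
            for a in ages:
                for c in cd4s:
                    k += 1
                    rows.append((f"P{k}", 12, 1, "observed", s, a, c, "EFV"))
        table = _mini_table(rows)
        est = standardized_predictions(sample, table, weeks=[96], regimens=["DTG"])[0]
        # brute force: loop persons, average per draw
        acc = np.zeros(sample.n_draws)
        for _, r in table.iterrows():
            x = design_row(dict(regimen="DTG", week=96, sex=r.sex,
                                age_group=r.age_group, cd4_group=r.cd4_group),
                           sample.spec)
            acc += marginal_probability(sample.beta @ x, sample.sigma_u)
        acc /= len(table)
        assert est.point == pytest.approx(float(np.median(acc)), rel=1e-12)
        assert est.lower == pytest.approx(float(np.quantile(acc, 0.025)), rel=1e-9)

    def test_nonstandardized_singleton_stratum(self):
        sample = _random_sample(S=20, seed=8)
        rows = [("P1", 12, 1, "observed", "male", "40+", ">=350", "DTG")]
        table = _mini_table(rows)
        with pytest.warns(UserWarning):  # all other strata empty
            ests = nonstandardized_predictions(sample, table)
        assert len(ests) == 1
        x = design_row(dict(regimen="DTG", week=12, sex="male", age_group="40+",
                            cd4_group=">=350"), sample.spec)
        draws = marginal_probability(sample.beta @ x, sample.sigma_u)
        assert ests[0].point == pytest.approx(float(np.median(draws)), rel=1e-12)

    def test_confounding_direction(self):
        """When low-CD4 persons concentrate in one regimen, standardizing to
        the common covariate mix moves that regimen's prediction in the
        direction of the CD4 coefficient."""
        spec = ModelSpec(interactions=(("regimen", "week"),))
        cols = spec.column_names()
        beta = np.zeros(len(cols))
        beta[cols.index("cd4_group=>=350")] = 1.5   # high CD4 strongly helps
        sample = _toy_sample(beta[None, :], [0.8], spec)
        rows = [(f"A{i}", 12, 1, "observed", "female", "20-29", "<200", "ATVr")
                for i in range(8)]
        rows += [(f"B{i}", 12, 1, "observed", "female", "20-29", ">=350", "EFV")
                 for i in range(8)]
        table = _mini_table(rows)
        std = {e.labels["regimen"]: e.point
               for e in standardized_predictions(sample, table, weeks=[12])}
        nonstd = {e.labels["regimen"]: e.point
                  for e in nonstandardized_predictions(sample, table)}
        # ATV/r observed only in low-CD4 persons: standardization (half high
        # CD4) must raise its prediction
        assert std["ATVr"] > nonstd["ATVr"]

    def test_empty_table_rejected(self):
        sample = _random_sample(S=10, seed=9)
        with pytest.raises(DataValidationError):
            standardized_predictions(sample, _mini_table([]))


class TestCrudeProportion:
    def test_zero_successes(self):
        est = crude_proportion(0, 10)
        assert est.point == 0.0
        # Beta(1, 11) central interval: 1 - q^(1/11) quantile form
        assert est.lower == pytest.approx(1 - 0.975 ** (1 / 11), rel=1e-9)
        assert est.upper == pytest.approx(1 - 0.025 ** (1 / 11), rel=1e-9)
        assert est.upper == pytest.approx(0.285, abs=5e-4)

    def test_symmetric_at_half(self):
        est = crude_proportion(5, 10)
        assert est.point == 0.5
        assert est.lower == pytest.approx(1 - est.upper, rel=1e-9)

    def test_all_successes_mirror(self):
        est = crude_proportion(10, 10)
        assert est.point == 1.0
        assert est.upper == pytest.approx(1 - 0.0023, abs=5e-4)

    def test_invalid_inputs(self):
        with pytest.raises(DataValidationError):
            crude_proportion(1, 0)
        with pytest.raises(DataValidationError):
            crude_proportion(5, 4)

    def test_table_counts(self, small_table):
        table, _ = small_table
        ests = crude_proportions_table(table)
        frame = estimates_to_frame(ests)
        assert (frame["kind"] == "proportion").all()
        assert len(ests) == table.groupby(["week", "regimen"], observed=True).ngroups
        for e in ests:
            assert 0.0 <= e.lower <= e.point <= e.upper <= 1.0
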