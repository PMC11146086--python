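"""Hierarchical model: HDI, posterior summaries, diagnostics, recovery."""

import warnings
from dataclasses import replace

import arviz as az
import numpy as np
import pytest

import metainsight as mi
from metainsight.model import (CohortData, ModelSpec, PosteriorSummary,
                               SamplerConfig, fit_subject_mle)

QUICK = SamplerConfig(chains=2, draws=300, warmup=300)


def make_posterior(draws, conditions=("imagery",)):
    return PosteriorSummary(conditions=conditions, subject_ids=["a", "b"],
                            draws=draws, subject_draws={}, spec=ModelSpec(),
                            config=QUICK, seed=0)


def quiet_fit(fitter, data, config=QUICK, seed=7, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fitter(data, config=config, seed=seed, **kw)


class TestHdi:
    def test_standard_normal_quantiles(self, rng):
        lo, hi = mi.hdi(rng.standard_normal(100_000))
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_matches_arviz(self, rng):
        x = rng.gamma(2.0, 1.5, size=50_000)
        lo, hi = mi.hdi(x)
        ref = az.hdi(x, hdi_prob=0.95)
        assert lo == pytest.approx(ref[0], abs=0.02)
        assert hi == pytest.approx(ref[1], abs=0.02)

    def test_never_longer_than_equal_tailed(self, rng):
        x = rng.lognormal(0.0, 0.8, size=20_000)
        lo, hi = mi.hdi(x)
        q_lo, q_hi = np.quantile(x, [0.025, 0.975])
        assert (hi - lo) < (q_hi - q_lo)   # strictly shorter for skew

    def test_constant_sample_zero_width(self):
        lo, hi = mi.hdi(np.full(500, 3.2))
        assert lo == hi == pytest.approx(3.2)

    def test_mass_bounds(self, rng):
        with pytest.raises(ValueError, match="mass"):
            mi.hdi(rng.standard_normal(1000), mass=1.0)

    def test_too_few_draws(self):
        with pytest.raises(ValueError, match="at least 100"):
            mi.hdi(np.arange(50))


class TestAsymmetryArithmetic:
    def test_symmetric_criteria_give_zero(self):
        shape = (2, 100)
        post = make_posterior({
            "mu_dc2_plus_imagery": np.full(shape, 1.0),
            "mu_dc2_minus_imagery": np.full(shape, -1.0),
        })
        assert mi.asymmetry_posterior(post, "imagery", basis="mean") \
            == pytest.approx(np.zeros(200))

    def test_full_insight_truth_value(self):
        """At the full-insight imagery truth (c1=0, c2-=-0.6, c2+=1.0) the
        asymmetry is 1.0 - 0.6 = 0.4."""
        shape = (2, 100)
        post = make_posterior({
            "loc_dc2_plus_imagery": np.full(shape, 1.0),
            "loc_dc2_minus_imagery": np.full(shape, -0.6),
        })
        a = mi.asymmetry_posterior(post, "imagery", basis="location")
        assert a == pytest.approx(np.full(200, 0.4))

    def test_no_insight_truth_is_zero(self):
        shape = (2, 100)
        post = make_posterior({
            "loc_dc2_plus_imagery": np.full(shape, 0.8),
            "loc_dc2_minus_imagery": np.full(shape, -0.8),
        })
        assert mi.asymmetry_posterior(post, "imagery") \
            == pytest.approx(np.zeros(200))

    def test_missing_condition(self):
        post = make_posterior({"mu_dc2_plus_imagery": np.zeros((2, 100))})
        with pytest.raises(KeyError):
            mi.asymmetry_posterior(post, "nope")

    def test_unknown_basis(self):
        post = make_posterior({"mu_dc2_plus_imagery": np.zeros((2, 100))})
        with pytest.raises(ValueError, match="basis"):
            mi.asymmetry_posterior(post, "imagery", basis="median")


class TestConditionDifference:
    def test_same_condition_is_zero(self):
        post = make_posterior(
            {"mu_dc2_plus_imagery": np.random.default_rng(0)
             .normal(size=(2, 200))})
        diff, (lo, hi) = mi.condition_difference(
            post, "mu_dc2_plus", "imagery", "imagery")
        assert diff == pytest.approx(np.zeros(400))
        assert (lo, hi) == (0.0, 0.0)

    def test_missing_parameter(self):
        post = make_posterior({"mu_dc2_plus_imagery": np.zeros((2, 100))})
        with pytest.raises(KeyError):
            mi.condition_difference(post, "mu_dc2_plus", "imagery", "other")


class TestConvergenceCheck:
    def test_disjoint_chains_fail_with_message(self):
        draws = {}
        for p in ("mu_logM", "sigma_logM", "mu_dc2_minus",
                  "sigma_dc2_minus", "mu_dc2_plus", "sigma_dc2_plus"):
            draws[f"{p}_imagery"] = np.vstack(
                [np.zeros(10), np.full(10, 5.0)])
        report = mi.convergence_check(make_posterior(draws))
        assert not report.passed
        assert "R-hat" in report.message

    def test_single_chain_limited(self):
        draws = {}
        for p in ("mu_logM", "sigma_logM", "mu_dc2_minus",
                  "sigma_dc2_minus", "mu_dc2_plus", "sigma_dc2_plus"):
            draws[f"{p}_imagery"] = np.random.default_rng(0) \
                .normal(size=(1, 500))
        report = mi.convergence_check(make_posterior(draws))
        assert not report.passed
        assert "single chain" in report.message


class TestFitValidation:
    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="at least 2"):
            CohortData(conditions=("a",), subject_ids=["s0"],
                       counts={"a": np.zeros((1, 2, 2, 2))},
                       d_prime={"a": np.ones(1)}, c1={"a": np.zeros(1)})

    def test_malformed_counts(self):
        with pytest.raises(ValueError, match="shape"):
            CohortData(conditions=("a",), subject_ids=["s0", "s1"],
                       counts={"a": np.zeros((2, 2, 2))},
                       d_prime={"a": np.ones(2)}, c1={"a": np.zeros(2)})


class TestInsightFit:
    def test_reduced_cohort_recovers_qualitative_truth(self, h1_small_fit,
                                                       h1_small_cohort):
        """On a 25-subject full-insight cohort the asymmetry posterior
        tracks the cohort's own sample asymmetry and the group distance
        means track the sample distances."""
        dp_true = np.mean([s["imagery"].c2_plus - s["imagery"].c1
                           for s in h1_small_cohort.subjects])
        dm_true = np.mean([s["imagery"].c2_minus - s["imagery"].c1
                           for s in h1_small_cohort.subjects])
        a = mi.asymmetry_posterior(h1_small_fit, "imagery", basis="mean")
        assert a.mean() == pytest.approx(dp_true - abs(dm_true), abs=0.15)
        assert h1_small_fit.mean_of("mu_dc2_plus_imagery") \
            == pytest.approx(dp_true, abs=0.2)
        assert h1_small_fit.mean_of("mu_dc2_minus_imagery") \
            == pytest.approx(dm_true, abs=0.2)

    def test_condition_difference_of_dc2_contains_zero(self, h1_small_fit):
        """Under full insight the confidence criteria are identical across
        conditions, so the between-condition dc2+ difference straddles 0."""
        _, (lo, hi) = mi.condition_difference(
            h1_small_fit, "mu_dc2_plus", "no_imagery", "imagery")
        assert lo < 0 < hi

    def test_summary_frame_contents(self, h1_small_fit):
        frame = h1_small_fit.summary_frame()
        assert {"parameter", "mean", "hdi_low", "hdi_high", "rhat",
                "ess_bulk"} <= set(frame.columns)
        assert (frame["hdi_low"] <= frame["hdi_high"]).all()
        assert "mu_dc2_plus_imagery" in set(frame["parameter"])

    def test_subject_shrinkage_toward_group(self, h1_small_fit,
                                            h1_small_cohort):
        """Subject-level log M posterior means sit between their
        maximum-likelihood values and the group mean (partial pooling)."""
        post = h1_small_fit
        cond = "imagery"
        data = CohortData.from_cohort(h1_small_cohort)
        group = post.mean_of(f"mu_logM_{cond}")
        post_means = post.subject_draws[f"logM_{cond}"].mean(axis=(0, 1))
        mles = np.array([
            fit_subject_mle(data.counts[cond][s], data.d_prime[cond][s],
                            data.c1[cond][s])[0]
            for s in range(data.n_subjects)
        ])
        # average shrinkage: posterior means are closer to the group mean
        assert np.abs(post_means - group).mean() \
            < np.abs(mles - group).mean()
        between = ((post_means - mles) * (group - mles) >= -1e-6)
        assert between.mean() >= 0.6

    def test_symmetric_data_gives_symmetric_asymmetry(self):
        """Identical subjects with exactly symmetric criteria: the
        asymmetry posterior is centred on 0 within Monte-Carlo error."""
        scen = replace(mi.make_scenario("no_insight"),
                       sigma_type1=1e-12, sigma_type2=1e-12)
        cohort = mi.simulate_cohort(scen.with_size(n_subjects=10), seed=4,
                                    mode="expected")
        post = quiet_fit(mi.fit_insight_model,
                         CohortData.from_cohort(cohort))
        a = mi.asymmetry_posterior(post, "imagery", basis="mean")
        a_cd = a.reshape(QUICK.chains, -1)
        mcse = a.std() / np.sqrt(max(float(az.ess(a_cd)), 4.0))
        assert abs(a.mean()) < 3 * mcse + 0.02

    def test_seeded_rerun_reproduces_diagnostics(self):
        scen = mi.make_scenario("no_insight").with_size(n_subjects=6)
        cohort = mi.simulate_cohort(scen, seed=12, mode="expected")
        data = CohortData.from_cohort(cohort)
        cfg = SamplerConfig(chains=2, draws=150, warmup=150)
        a = quiet_fit(mi.fit_insight_model, data, config=cfg, seed=21)
        b = quiet_fit(mi.fit_insight_model, data, config=cfg, seed=21)
        for key in a.draws:
            assert np.array_equal(np.asarray(a.draws[key]),
                                  np.asarray(b.draws[key]))


class TestStandardMratioFit:
    def test_unit_mratio_recovery(self):
        """Data generated at M = 1: the group M-ratio HDI covers 1."""
        scen = replace(mi.make_scenario("no_insight"), m_ratio=1.0)
        cohort = mi.simulate_cohort(scen.with_size(n_subjects=30), seed=8,
                                    mode="expected")
        post = quiet_fit(mi.fit_standard_mratio,
                         CohortData.from_cohort(cohort),
                         config=SamplerConfig(chains=2, draws=400,
                                              warmup=400), seed=3)
        lo, hi = mi.hdi(post.flat("mratio_imagery"))
        assert lo < 1.0 < hi

    def test_symmetric_model_has_zero_asymmetry(self, h1_small_cohort):
        post = quiet_fit(mi.fit_standard_mratio,
                         CohortData.from_cohort(h1_small_cohort))
        a = mi.asymmetry_posterior(post, "imagery", basis="mean")
        assert np.abs(a).max() < 1e-12

    def test_shared_type1_constants_with_insight_fit(self, h1_small_cohort):
        """Both model variants consume identical Type-1 point estimates."""
        d1 = CohortData.from_cohort(h1_small_cohort)
        d2 = CohortData.from_cohort(h1_small_cohort)
        for cond in d1.conditions:
            assert np.array_equal(d1.d_prime[cond], d2.d_prime[cond])
            assert np.array_equal(d1.c1[cond], d2.c1[cond])

    def test_mratio_coverage_across_cohorts(self):
        """Across 20 seeded scenario cohorts (reduced size), the group
        M-ratio HDI covers each cohort's own generating value (the
        geometric mean of its subject M-ratios) in >= 90% of runs, and
        the posterior mean stays near the group setting of 0.8."""
        scen = mi.make_scenario("no_insight").with_size(n_subjects=20)
        cfg = SamplerConfig(chains=2, draws=300, warmup=300)
        covered, means = 0, []
        root = np.random.SeedSequence(2024)
        for child in root.spawn(20):
            rng = np.random.default_rng(child)
            cohort = mi.simulate_cohort(scen, mode="expected", rng=rng)
            truth = float(np.exp(np.mean(
                [np.log(s["imagery"].m_ratio) for s in cohort.subjects])))
            post = quiet_fit(mi.fit_standard_mratio,
                             CohortData.from_cohort(cohort), config=cfg,
                             seed=int(child.generate_state(1)[0] % 2**31))
            lo, hi = mi.hdi(post.flat("mratio_imagery"))
            covered += int(lo <= truth <= hi)
            means.append(post.mean_of("mratio_imagery"))
        assert covered >= 18
        assert np.mean(means) == pytest.approx(0.8, abs=0.08)
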