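"""Synthetic cohorts: scenario tables, subject draws, count and trial synthesis."""

from dataclasses import replace

import numpy as np
import pytest

import metainsight as mi
from metainsight.sdt import binarize_trials


class TestScenarios:
    def test_no_insight_table(self):
        scen = mi.make_scenario("no_insight")
        assert scen.c1 == {"no_imagery": 0.2, "imagery": 0.0}
        assert scen.c2_minus == {"no_imagery": -0.6, "imagery": -0.8}
        assert scen.c2_plus == {"no_imagery": 1.0, "imagery": 0.8}

    def test_full_insight_table(self):
        scen = mi.make_scenario("full_insight")
        assert scen.c2_minus["imagery"] == -0.6
        assert scen.c2_plus["imagery"] == 1.0
        # the imagery confidence criteria equal the no-imagery ones
        assert scen.c2_minus["imagery"] == scen.c2_minus["no_imagery"]
        assert scen.c2_plus["imagery"] == scen.c2_plus["no_imagery"]

    def test_shared_defaults(self):
        for name in ("no_insight", "full_insight"):
            scen = mi.make_scenario(name)
            assert (scen.d_prime, scen.m_ratio) == (2.5, 0.8)
            assert (scen.sigma_type1, scen.sigma_type2) == (0.2, 0.5)
            assert (scen.n_subjects, scen.n_trials_per_condition) == (100, 96)

    def test_no_imagery_row_identical_between_scenarios(self):
        a = mi.make_scenario("no_insight")
        b = mi.make_scenario("full_insight")
        for field in ("c1", "c2_minus", "c2_plus"):
            assert getattr(a, field)["no_imagery"] == \
                getattr(b, field)["no_imagery"]

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            mi.make_scenario("partial_insight")


class TestSampleSubjects:
    def test_zero_sigma_degenerates_to_group_values(self, rng):
        scen = replace(mi.make_scenario("no_insight"),
                       sigma_type1=1e-12, sigma_type2=1e-12, n_subjects=5)
        subs = mi.sample_subjects(scen, rng)
        for s in subs:
            for cond in scen.conditions:
                assert s[cond].d_prime == pytest.approx(2.5, abs=1e-9)
                assert s[cond].c1 == pytest.approx(scen.c1[cond], abs=1e-9)
                assert s[cond].m_ratio == pytest.approx(0.8, abs=1e-9)

    def test_seed_determinism(self):
        scen = mi.make_scenario("full_insight").with_size(n_subjects=10)
        a = mi.sample_subjects(scen, np.random.default_rng(3))
        b = mi.sample_subjects(scen, np.random.default_rng(3))
        assert a[4]["imagery"] == b[4]["imagery"]

    def test_ordering_always_enforced(self, rng):
        scen = mi.make_scenario("no_insight").with_size(n_subjects=500)
        for s in mi.sample_subjects(scen, rng):
            for cond in scen.conditions:
                p = s[cond]
                assert p.c2_minus < p.c1 < p.c2_plus
                assert p.d_prime > 0 and p.m_ratio > 0

    def test_law_of_large_numbers(self):
        """Sample means of the drawn parameters approach the group values
        (the criterion draws carry a small truncation shift away from
        zero, bounded by the rejection rate)."""
        scen = mi.make_scenario("no_insight").with_size(n_subjects=10_000)
        subs = mi.sample_subjects(scen, np.random.default_rng(99))
        d = np.array([s["imagery"].d_prime for s in subs])
        c1 = np.array([s["imagery"].c1 for s in subs])
        m = np.array([s["imagery"].m_ratio for s in subs])
        assert d.mean() == pytest.approx(2.5, abs=4 * 0.2 / 100)
        assert m.mean() == pytest.approx(0.8, abs=0.02)
        # c1 enters the joint ordering constraint; allow the small
        # conditioning shift on top of 4 SE
        assert c1.mean() == pytest.approx(0.0, abs=4 * 0.2 / 100 + 0.02)


class TestSimulateCounts:
    def test_expected_mode_conserves_trials(self):
        params = mi.make_scenario("no_insight").group_params("imagery")
        table = mi.simulate_counts(params, n_trials=96, prevalence=0.5)
        assert table.per_stimulus() == pytest.approx([48.0, 48.0])
        assert table.total == pytest.approx(96.0)

    def test_huge_sensitivity_limit(self):
        params = mi.SubjectParams(d_prime=8.0, c1=0.0, c2_minus=-2.0,
                                  c2_plus=2.0, m_ratio=1.0)
        table = mi.simulate_counts(params, n_trials=96)
        # errors (misses and false alarms) essentially vanish
        assert table.counts[1, 0].sum() == pytest.approx(0.0, abs=1e-2)
        assert table.counts[0, 1].sum() == pytest.approx(0.0, abs=1e-2)

    def test_multinomial_mean_matches_expected(self):
        params = mi.make_scenario("no_insight").group_params("no_imagery")
        expected = mi.simulate_counts(params, mode="expected").counts
        rng = np.random.default_rng(17)
        reps = 4000
        acc = np.zeros((2, 2, 2))
        for _ in range(reps):
            acc += mi.simulate_counts(params, mode="multinomial",
                                      rng=rng).counts
        mean = acc / reps
        n_stim = 48.0
        p = expected / n_stim
        se = np.sqrt(np.clip(n_stim * p * (1 - p), 1e-9, None) / reps)
        assert np.all(np.abs(mean - expected) <= 3 * se + 1e-6)

    def test_invalid_prevalence(self):
        params = mi.make_scenario("no_insight").group_params("imagery")
        with pytest.raises(ValueError, match="prevalence"):
            mi.simulate_counts(params, prevalence=1.0)

    def test_multinomial_needs_rng(self):
        params = mi.make_scenario("no_insight").group_params("imagery")
        with pytest.raises(ValueError, match="rng"):
            mi.simulate_counts(params, mode="multinomial")


class TestSummarizeMeanConfidence:
    def test_all_high(self):
        counts = np.zeros((2, 2, 2))
        counts[:, :, 1] = 5.0
        props = mi.summarize_mean_confidence(mi.ConfidenceCounts(counts))
        assert props == {"absent": 1.0, "present": 1.0}

    def test_direct_count(self):
        counts = np.zeros((2, 2, 2))
        counts[0, 0, 1] = 2.0   # high-confidence correct rejections
        counts[1, 0, 1] = 1.0   # high-confidence miss
        counts[0, 0, 0] = 1.0   # low-confidence correct rejection
        props = mi.summarize_mean_confidence(mi.ConfidenceCounts(counts))
        assert props["absent"] == pytest.approx(0.75)
        assert np.isnan(props["present"])   # no present responses: flagged

    def test_no_insight_sign_pattern(self):
        """At the group parameter values, no-insight imagery raises
        present-response confidence and lowers absent-response confidence
        relative to no imagery."""
        scen = mi.make_scenario("no_insight")
        props = {
            cond: mi.summarize_mean_confidence(
                mi.simulate_counts(scen.group_params(cond)))
            for cond in scen.conditions
        }
        assert props["imagery"]["present"] > props["no_imagery"]["present"]
        assert props["imagery"]["absent"] < props["no_imagery"]["absent"]

    def test_full_insight_sign_pattern(self):
        scen = mi.make_scenario("full_insight")
        props = {
            cond: mi.summarize_mean_confidence(
                mi.simulate_counts(scen.group_params(cond)))
            for cond in scen.conditions
        }
        assert props["imagery"]["present"] < props["no_imagery"]["present"]
        assert props["imagery"]["absent"] > props["no_imagery"]["absent"]


class TestSimulateTrials:
    def test_block_structure(self, rng):
        params = mi.make_scenario("no_insight").group_params("imagery")
        trials = mi.simulate_trials(params, mi.TrialDesign(), rng)
        assert len(trials) == 96
        assert trials["block"].nunique() == 4
        assert (trials.groupby("block").size() == 24).all()
        assert set(trials.columns) >= {"subject_id", "condition", "block",
                                       "stimulus", "response", "confidence",
                                       "rt_ms", "imagery_check_pass"}

    def test_seed_gives_byte_identical_csv(self):
        scen = mi.make_scenario("no_insight").with_size(n_subjects=3)
        a = mi.cohort_trials(scen, seed=11).to_csv(index=False)
        b = mi.cohort_trials(scen, seed=11).to_csv(index=False)
        assert a == b

    def test_cohort_round_trip(self):
        """Binarizing every subject's synthesized ratings recovers a count
        table whose Type-1 collapse matches the trial stimulus/response
        columns."""
        scen = mi.make_scenario("full_insight").with_size(n_subjects=4)
        trials = mi.cohort_trials(scen, seed=2)
        binned = binarize_trials(trials)
        for (_, _), grp in binned.groupby(["subject_id", "condition"]):
            table = mi.tabulate_counts(grp)
            assert table.total == 96
            det = table.detection_counts()
            assert det.n_hit == ((grp["stimulus"] == 1)
                                 & (grp["response"] == 1)).sum()


class TestSimulatedCohort:
    def test_counts_frame_shape(self):
        scen = mi.make_scenario("no_insight").with_size(n_subjects=3)
        cohort = mi.simulate_cohort(scen, seed=1)
        frame = cohort.counts_frame()
        assert len(frame) == 3 * 2 * 8
        assert frame.groupby(["subject_id", "condition"])["count"].sum() \
            .eq(96).all()

    def test_expected_mode_deterministic_given_subjects(self):
        scen = mi.make_scenario("no_insight").with_size(n_subjects=3)
        a = mi.simulate_cohort(scen, seed=9)
        b = mi.simulate_cohort(scen, seed=9)
        for cond in scen.conditions:
            for s in range(3):
                assert np.array_equal(a.counts[cond][s].counts,
                                      b.counts[cond][s].counts)
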