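"""End-to-end study pipeline.

Exclusion filtering of trial-level data, first-order paired contrasts,
the condition x response interaction contrast on confidence ("confidence
effect"), the replicated H0/H1 simulation study, and the normal-
approximation power calculation for a paired design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from . import simulate as sim
from .model import (CohortData, ModelSpec, SamplerConfig, asymmetry_posterior,
                    convergence_check, fit_insight_model, hdi)
from .sdt import binarize_trials, estimate_type1, tabulate_counts

__all__ = [
    "ExclusionConfig",
    "ExclusionReport",
    "ContrastResult",
    "SimulationStudySummary",
    "apply_exclusions",
    "confidence_effect",
    "first_order_contrasts",
    "power_required_n",
    "run_simulation_study",
    "cohort_confidence_measures",
    "cohort_type1_estimates",
]

REQUIRED_TRIAL_COLUMNS = ("subject_id", "condition", "block", "stimulus",
                          "response", "confidence", "imagery_check_pass")


@dataclass(frozen=True)
class ExclusionConfig:
    """Thresholds of the preprocessing filters.

    ``accuracy_threshold`` operationalizes "below chance" as the study's
    55% cutoff; ``confidence_repeat_threshold`` is the fraction of
    identical confidence ratings within one response class beyond which a
    subject is removed.
    """

    accuracy_threshold: float = 0.55
    min_passed_blocks: int = 2
    confidence_repeat_threshold: float = 0.9
    self_report_column: str = "self_report_ok"


@dataclass
class ExclusionReport:
    """Who was removed by which rule, in application order."""

    blocks_removed: list = field(default_factory=list)
    removed_accuracy: list = field(default_factory=list)          # rule (a)
    removed_imagery_checks: list = field(default_factory=list)    # rule (b)
    removed_self_report: list = field(default_factory=list)       # rule (c)
    removed_confidence_invariance: list = field(default_factory=list)  # (d)
    n_subjects_before: int = 0
    n_subjects_after: int = 0
    n_trials_before: int = 0
    n_trials_after: int = 0

    @property
    def removed_subjects(self) -> list:
        return (self.removed_accuracy + self.removed_imagery_checks
                + self.removed_self_report
                + self.removed_confidence_invariance)

    def to_dict(self) -> dict:
        return {
            "blocks_removed": [list(b) for b in self.blocks_removed],
            "removed_accuracy": list(self.removed_accuracy),
            "removed_imagery_checks": list(self.removed_imagery_checks),
            "removed_self_report": list(self.removed_self_report),
            "removed_confidence_invariance":
                list(self.removed_confidence_invariance),
            "n_subjects_before": self.n_subjects_before,
            "n_subjects_after": self.n_subjects_after,
            "n_trials_before": self.n_trials_before,
            "n_trials_after": self.n_trials_after,
        }


def apply_exclusions(trials: pd.DataFrame,
                     config: ExclusionConfig | None = None):
    """Apply the study's preprocessing filters.

    Order: (0) drop blocks whose imagery check failed, then remove
    subjects by (a) mean detection accuracy over conditions below the
    threshold, (b) fewer than ``min_passed_blocks`` passed-check blocks
    in any condition, (c) self-reported non-compliance (consumed from an
    optional flag column), (d) more than the threshold fraction of
    identical confidence ratings within either response class.

    Returns ``(filtered_trials, ExclusionReport)``.
    """
    config = config or ExclusionConfig()
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trials table lacks required columns: {missing}")

    report = ExclusionReport(
        n_subjects_before=trials["subject_id"].nunique(),
        n_trials_before=len(trials),
    )

    failed = trials["imagery_check_pass"] == 0
    report.blocks_removed = sorted(
        trials.loc[failed, ["subject_id", "condition", "block"]]
        .drop_duplicates().itertuples(index=False, name=None))
    data = trials.loc[~failed].copy()

    # (a) mean detection accuracy over conditions below threshold
    acc = (data.assign(correct=lambda d: (d["stimulus"] == d["response"])
                       .astype(float))
           .groupby(["subject_id", "condition"])["correct"].mean()
           .groupby("subject_id").mean())
    report.removed_accuracy = sorted(
        acc.index[acc < config.accuracy_threshold])
    data = data[~data["subject_id"].isin(report.removed_accuracy)]

    # (b) too few passed-check blocks in any condition
    conditions = trials["condition"].unique()
    blocks = (data.groupby(["subject_id", "condition"])["block"]
              .nunique().unstack("condition"))
    blocks = blocks.reindex(columns=conditions).fillna(0)
    bad_b = blocks.index[(blocks < config.min_passed_blocks).any(axis=1)]
    report.removed_imagery_checks = sorted(bad_b)
    data = data[~data["subject_id"].isin(bad_b)]

    # (c) self-reported non-compliance, if the flag column is present
    if config.self_report_column in data.columns:
        flags = data.groupby("subject_id")[config.self_report_column].min()
        report.removed_self_report = sorted(flags.index[flags == 0])
        data = data[~data["subject_id"].isin(report.removed_self_report)]

    # (d) near-constant confidence within a response class
    bad_d = []
    for subj, grp in data.groupby("subject_id"):
        for _, cls in grp.groupby("response"):
            frac = cls["confidence"].value_counts(normalize=True).iloc[0]
            if frac > config.confidence_repeat_threshold:
                bad_d.append(subj)
                break
    report.removed_confidence_invariance = sorted(bad_d)
    data = data[~data["subject_id"].isin(bad_d)]

    report.n_subjects_after = data["subject_id"].nunique()
    report.n_trials_after = len(data)
    return data.reset_index(drop=True), report


@dataclass
class ContrastResult:
    """One-sample / paired t-contrast with effect size and CI.

    ``effect_size`` is Cohen's d for within-subject contrasts
    (mean / SD of the per-subject contrast values); the CI is the
    t-based 95% interval of the mean contrast.
    """

    statistic: float
    df: int
    p_value: float
    effect_size: float
    ci_low: float
    ci_high: float
    contrasts: np.ndarray

    @property
    def n(self) -> int:
        return self.df + 1


def _one_sample_contrast(values: np.ndarray, ci_mass: float = 0.95):
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 subjects for a contrast")
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        # degenerate contrast: identical values for every subject
        sign = float(np.sign(mean))
        t_stat = sign * np.inf if mean != 0 else 0.0
        p = 0.0 if mean != 0 else 1.0
        lo = hi = mean
        d = sign * np.inf if mean != 0 else 0.0
    else:
        t_stat, p = stats.ttest_1samp(values, 0.0)
        d = mean / sd
        half = stats.t.ppf(0.5 + ci_mass / 2, n - 1) * sd / math.sqrt(n)
        lo, hi = mean - half, mean + half
    return ContrastResult(statistic=float(t_stat), df=n - 1,
                          p_value=float(p), effect_size=float(d),
                          ci_low=float(lo), ci_high=float(hi),
                          contrasts=values)


def confidence_effect(measures: pd.DataFrame, cond_imagery: str,
                      cond_baseline: str,
                      value_col: str = "value") -> ContrastResult:
    """Condition x response interaction contrast on a per-subject measure.

    ``measures`` holds one row per subject x condition x response with
    the measure in ``value_col`` (mean confidence, high-confidence
    proportion, or mean RT — the contrast applies to any of them).  The
    per-subject interaction is

        (v[imagery, present] - v[imagery, absent])
        - (v[baseline, present] - v[baseline, absent])

    tested against 0 with a one-sample t-test.  Positive t reflects the
    no-insight pattern (confidence follows the criterion shift); negative
    t the insight pattern.  Subjects missing any of the four cells are
    dropped with a warning.
    """
    sub = measures[measures["condition"].isin([cond_imagery, cond_baseline])]
    wide = sub.pivot_table(index="subject_id", columns=["condition", "response"],
                           values=value_col, aggfunc="mean")
    needed = [(cond_imagery, 1), (cond_imagery, 0),
              (cond_baseline, 1), (cond_baseline, 0)]
    for cell in needed:
        if cell not in wide.columns:
            wide[cell] = np.nan
    complete = wide.dropna(subset=needed)
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} subject(s) with incomplete "
                      "condition x response cells", stacklevel=2)
    inter = ((complete[(cond_imagery, 1)] - complete[(cond_imagery, 0)])
             - (complete[(cond_baseline, 1)] - complete[(cond_baseline, 0)]))
    return _one_sample_contrast(inter.to_numpy())


def first_order_contrasts(estimates: pd.DataFrame,
                          pairs=None) -> dict:
    """Paired t-contrasts of d' and criterion between condition pairs.

    ``estimates`` holds one row per subject x condition with columns
    ``d_prime`` and ``criterion``.  Returns a dict keyed by
    ``(cond_a, cond_b, measure)`` with the contrast ``a - b``.
    """
    conditions = list(pd.unique(estimates["condition"]))
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(conditions)
                 for b in conditions[i + 1:]]
    out = {}
    for a, b in pairs:
        for measure in ("d_prime", "criterion"):
            wide = estimates.pivot_table(index="subject_id",
                                         columns="condition",
                                         values=measure).dropna(subset=[a, b])
            out[(a, b, measure)] = _one_sample_contrast(
                (wide[a] - wide[b]).to_numpy())
    return out


def power_required_n(effect_size: float, alpha: float = 0.05,
                     power: float = 0.9) -> int:
    """Required sample size for a paired/one-sample design.

    Normal approximation: n = ceil( ((z_{1-alpha/2} + z_power) / d)^2 ),
    two-sided alpha.
    """
    if effect_size <= 0:
        raise ValueError("effect_size must be positive")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    z = ndtri(1 - alpha / 2) + ndtri(power)
    return max(1, math.ceil((z / effect_size) ** 2))


def cohort_confidence_measures(cohort) -> pd.DataFrame:
    """Per-subject high-confidence proportion by condition and response.

    One row per subject x condition x response (0 = absent, 1 = present)
    with the proportion in ``value`` — the measure the simulation study
    feeds to :func:`confidence_effect`.
    """
    rows = []
    for cond in cohort.conditions:
        for s, table in enumerate(cohort.counts[cond]):
            props = sim.summarize_mean_confidence(table)
            for resp, name in ((0, "absent"), (1, "present")):
                rows.append({"subject_id": f"s{s:03d}", "condition": cond,
                             "response": resp, "value": props[name]})
    return pd.DataFrame(rows)


def cohort_type1_estimates(cohort) -> pd.DataFrame:
    """Type-1 d'/criterion estimates per subject x condition."""
    rows = []
    for cond in cohort.conditions:
        for s, table in enumerate(cohort.counts[cond]):
            est = estimate_type1(table.detection_counts())
            rows.append({
                "subject_id": f"s{s:03d}", "condition": cond,
                "d_prime": est.d_prime, "criterion": est.criterion,
                "hit_rate": est.hit_rate, "fa_rate": est.fa_rate,
                "correction_applied": est.correction_applied,
            })
    return pd.DataFrame(rows)


@dataclass
class SimulationStudySummary:
    """Replicate-level results and aggregates of the H0/H1 study."""

    replicates: pd.DataFrame
    n_reps: int
    fitted: bool
    seed: int | None

    def aggregate(self) -> pd.DataFrame:
        """Per scenario: sign/significance proportions of the confidence
        effect and, if fitted, asymmetry-HDI coverage of zero."""
        rows = []
        for scen, grp in self.replicates.groupby("scenario"):
            row = {
                "scenario": scen,
                "n_reps": len(grp),
                "prop_t_positive": float((grp["t"] > 0).mean()),
                "prop_t_negative": float((grp["t"] < 0).mean()),
                "prop_p_below_05": float((grp["p"] < 0.05).mean()),
            }
            if self.fitted:
                row["prop_hdi_contains_0"] = float(
                    ((grp["a_hdi_low"] <= 0)
                     & (grp["a_hdi_high"] >= 0)).mean())
                row["prop_hdi_above_0"] = float((grp["a_hdi_low"] > 0).mean())
            rows.append(row)
        return pd.DataFrame(rows)


def run_simulation_study(scenarios=("no_insight", "full_insight"),
                         n_reps: int = 20, fit: bool = False,
                         seed: int | None = None,
                         n_subjects: int | None = None,
                         n_trials: int | None = None,
                         mode: str = "expected",
                         spec: ModelSpec | None = None,
                         sampler_config: SamplerConfig | None = None,
                         ) -> SimulationStudySummary:
    """Repeat the H0/H1 simulations and collect the two insight readouts.

    Per replicate: a fresh cohort, the confidence-effect t-statistic
    (imagery vs no-imagery interaction), and — with ``fit=True`` — the
    hierarchical fit's 95% HDI of the imagery asymmetry A.  Scenario
    names are resolved via :func:`metainsight.simulate.make_scenario`;
    cohort size defaults to the scenario's (100 subjects x 96 trials).
    """
    if fit and sampler_config is None:
        sampler_config = SamplerConfig(chains=2, draws=600, warmup=600)
    root = np.random.SeedSequence(seed)
    rows = []
    for scen_name in scenarios:
        scenario = sim.make_scenario(scen_name).with_size(n_subjects, n_trials)
        for rep, child in enumerate(root.spawn(n_reps)):
            rng = np.random.default_rng(child)
            cohort = sim.simulate_cohort(scenario, mode=mode, rng=rng)
            contrast = confidence_effect(
                cohort_confidence_measures(cohort),
                cond_imagery=sim.IMAGERY, cond_baseline=sim.NO_IMAGERY)
            row = {"scenario": scen_name, "rep": rep,
                   "t": contrast.statistic, "df": contrast.df,
                   "p": contrast.p_value, "d": contrast.effect_size}
            if fit:
                fit_seed = int(child.generate_state(1)[0] % (2 ** 31))
                post = fit_insight_model(CohortData.from_cohort(cohort),
                                         spec=spec, config=sampler_config,
                                         seed=fit_seed)
                a = asymmetry_posterior(post, sim.IMAGERY)
                lo, hi = hdi(a)
                diag = convergence_check(post)
                row.update(a_mean=float(a.mean()), a_hdi_low=lo,
                           a_hdi_high=hi,
                           rhat_max=float(diag.table["rhat"].max()))
            rows.append(row)
    return SimulationStudySummary(replicates=pd.DataFrame(rows),
                                  n_reps=n_reps, fitted=fit, seed=seed)


def analyze_trials(trials: pd.DataFrame,
                   exclusion_config: ExclusionConfig | None = None,
                   fit: bool = False,
                   cond_imagery: str | None = None,
                   cond_baseline: str | None = None,
                   spec: ModelSpec | None = None,
                   sampler_config: SamplerConfig | None = None,
                   seed: int | None = None) -> dict:
    """Full trial-table pipeline: filter, bin, estimate, contrast, fit.

    Returns a dict with the exclusion report, per-subject Type-1
    estimates, first-order contrasts, the confidence-effect contrast
    (raw-confidence means per response class) and, with ``fit=True``,
    the hierarchical posterior summary.
    """
    filtered, report = apply_exclusions(trials, exclusion_config)
    binned = binarize_trials(filtered)

    conditions = list(pd.unique(binned["condition"]))
    if cond_imagery is None:
        others = [c for c in conditions if c != sim.NO_IMAGERY]
        cond_imagery = others[0] if others else conditions[0]
    if cond_baseline is None:
        cond_baseline = (sim.NO_IMAGERY if sim.NO_IMAGERY in conditions
                         else conditions[-1])

    est_rows, count_rows = [], []
    for (subj, cond), grp in binned.groupby(["subject_id", "condition"]):
        counts = tabulate_counts(grp)
        est = estimate_type1(counts.detection_counts())
        est_rows.append({"subject_id": subj, "condition": cond,
                         "d_prime": est.d_prime, "criterion": est.criterion,
                         "hit_rate": est.hit_rate, "fa_rate": est.fa_rate,
                         "correction_applied": est.correction_applied})
        count_rows.append(counts.to_frame(subject_id=subj, condition=cond))
    estimates = pd.DataFrame(est_rows)
    counts_long = pd.concat(count_rows, ignore_index=True)

    conf_measures = (binned.groupby(["subject_id", "condition", "response"])
                     ["confidence"].mean().rename("value").reset_index())
    results = {
        "exclusion_report": report,
        "type1_estimates": estimates,
        "counts": counts_long,
        "first_order_contrasts": first_order_contrasts(estimates),
        "confidence_effect": confidence_effect(
            conf_measures, cond_imagery=cond_imagery,
            cond_baseline=cond_baseline),
    }
    if "rt_ms" in binned.columns:
        rt_measures = (binned.groupby(["subject_id", "condition", "response"])
                       ["rt_ms"].mean().rename("value").reset_index())
        results["rt_effect"] = confidence_effect(
            rt_measures, cond_imagery=cond_imagery,
            cond_baseline=cond_baseline)
    if fit:
        data = CohortData.from_frames(counts_long, estimates)
        results["posterior"] = fit_insight_model(
            data, spec=spec, config=sampler_config, seed=seed)
    return results
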