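"""Synthetic cohorts with the study's generative structure.

The simulation study compares two hypotheses about metacognitive insight
into an imagery-induced liberal shift of the detection criterion:

* **no insight (H0)** — confidence criteria move in tandem with the
  decision criterion, so their distances from c1 stay symmetric
  (imagery: c1 = 0, c2- = -0.8, c2+ = 0.8);
* **full insight (H1)** — confidence criteria stay anchored at their
  no-imagery positions despite the c1 shift, creating a positive
  asymmetry (imagery: c1 = 0, c2- = -0.6, c2+ = 1.0).

Both scenarios share the no-imagery condition (c1 = 0.2, c2- = -0.6,
c2+ = 1.0), a group d' of 2.5 and M-ratio of 0.8, with 100 subjects of 96
trials per condition and Gaussian between-subject spread (sigma 0.2 for
Type-1 parameters, 0.5 for Type-2 parameters).

Subject-level generation draws d' and meta-d' once per subject (meta-d'
~ N(M x d', sigma2), so M-ratios centre on the group value) and criteria
per condition, redrawing any set violating c2- < c1 < c2+ or a
non-positive sensitivity.  Count tables compose first-order response
probabilities from (d', c1) with the meta-level confidence conditionals
from :mod:`metainsight.type2`, either as expected (continuous) counts or
as multinomial draws.  A trial-level synthesizer emits continuous 0-100
confidence ratings that re-binarize to the generating counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sdt import ConfidenceCounts
from .type2 import SubjectParams, cell_probabilities, response_probabilities_type1

__all__ = [
    "GroupScenario",
    "TrialDesign",
    "SimulatedCohort",
    "make_scenario",
    "sample_subjects",
    "simulate_counts",
    "summarize_mean_confidence",
    "simulate_trials",
    "simulate_cohort",
    "cohort_trials",
]

NO_IMAGERY = "no_imagery"
IMAGERY = "imagery"

#: cap on rejection redraws for out-of-order criterion draws
MAX_REDRAWS = 1000


@dataclass(frozen=True)
class GroupScenario:
    """Group-level parameter set for one simulated study."""

    insight_label: str
    c1: dict
    c2_minus: dict
    c2_plus: dict
    d_prime: float = 2.5
    m_ratio: float = 0.8
    sigma_type1: float = 0.2
    sigma_type2: float = 0.5
    n_subjects: int = 100
    n_trials_per_condition: int = 96

    def __post_init__(self) -> None:
        if self.sigma_type1 < 0 or self.sigma_type2 < 0:
            raise ValueError("between-subject sigmas must be non-negative")
        for cond in self.conditions:
            if not (self.c2_minus[cond] < self.c1[cond] < self.c2_plus[cond]):
                raise ValueError(f"criteria out of order for condition {cond!r}")

    @property
    def conditions(self) -> tuple:
        return tuple(self.c1.keys())

    def group_params(self, condition: str) -> SubjectParams:
        return SubjectParams(
            d_prime=self.d_prime,
            c1=self.c1[condition],
            c2_minus=self.c2_minus[condition],
            c2_plus=self.c2_plus[condition],
            m_ratio=self.m_ratio,
        )

    def with_size(self, n_subjects=None, n_trials=None) -> "GroupScenario":
        """Copy with a different cohort size (parameters untouched)."""
        out = self
        if n_subjects is not None:
            out = replace(out, n_subjects=int(n_subjects))
        if n_trials is not None:
            out = replace(out, n_trials_per_condition=int(n_trials))
        return out


def make_scenario(name: str) -> GroupScenario:
    """Built-in H0 (``no_insight``) / H1 (``full_insight``) scenarios.

    The no-imagery condition is identical in both; only the imagery
    condition's confidence criteria differ (symmetric +-0.8 under no
    insight; anchored at -0.6/1.0 under full insight).
    """
    shared = dict(c1={NO_IMAGERY: 0.2, IMAGERY: 0.0})
    if name == "no_insight":
        return GroupScenario(
            insight_label="no_insight",
            c2_minus={NO_IMAGERY: -0.6, IMAGERY: -0.8},
            c2_plus={NO_IMAGERY: 1.0, IMAGERY: 0.8},
            **shared,
        )
    if name == "full_insight":
        return GroupScenario(
            insight_label="full_insight",
            c2_minus={NO_IMAGERY: -0.6, IMAGERY: -0.6},
            c2_plus={NO_IMAGERY: 1.0, IMAGERY: 1.0},
            **shared,
        )
    raise ValueError(f"unknown scenario {name!r}; expected 'no_insight' or 'full_insight'")


def sample_subjects(scenario: GroupScenario, rng: np.random.Generator) -> list:
    """Draw per-subject parameters for every condition.

    Returns a list (length ``n_subjects``) of ``{condition: SubjectParams}``
    dicts.  d' and meta-d' are drawn once per subject and shared across
    conditions; the criterion deviations (for c1, c2-, c2+) are drawn once
    per subject and applied around each condition's group values, and are
    jointly redrawn while any condition's ordering is violated (cap 1000
    attempts).
    """
    s1, s2 = scenario.sigma_type1, scenario.sigma_type2
    n = scenario.n_subjects

    d = rng.normal(scenario.d_prime, s1, size=n)
    for _ in range(MAX_REDRAWS):
        bad = d <= 0
        if not bad.any():
            break
        d[bad] = rng.normal(scenario.d_prime, s1, size=int(bad.sum()))
    else:
        raise RuntimeError("could not draw positive d' within the redraw cap")

    meta_d = rng.normal(scenario.m_ratio * d, s2)
    for _ in range(MAX_REDRAWS):
        bad = meta_d <= 0
        if not bad.any():
            break
        meta_d[bad] = rng.normal(scenario.m_ratio * d[bad], s2)
    else:
        raise RuntimeError("could not draw positive meta-d' within the redraw cap")

    # Each subject's criterion deviations from the scenario-table values
    # are drawn once and applied in every condition: the scenarios encode
    # within-subject structure (criteria moving in tandem with, or staying
    # anchored against, the c1 shift), so a subject's idiosyncratic
    # criterion placement persists across conditions while its marginal
    # distribution per condition remains Normal(group value, sigma).
    conds = scenario.conditions
    eps_c1 = rng.normal(0.0, s1, size=n)
    dlt_m = rng.normal(0.0, s2, size=n)
    dlt_p = rng.normal(0.0, s2, size=n)
    for _ in range(MAX_REDRAWS):
        bad = np.zeros(n, dtype=bool)
        for cond in conds:
            c1 = scenario.c1[cond] + eps_c1
            bad |= ~((scenario.c2_minus[cond] + dlt_m < c1)
                     & (c1 < scenario.c2_plus[cond] + dlt_p))
        if not bad.any():
            break
        k = int(bad.sum())
        eps_c1[bad] = rng.normal(0.0, s1, size=k)
        dlt_m[bad] = rng.normal(0.0, s2, size=k)
        dlt_p[bad] = rng.normal(0.0, s2, size=k)
    else:
        raise RuntimeError(
            "could not draw ordered criteria within the redraw cap")

    out: list = [dict() for _ in range(n)]
    for cond in conds:
        for s in range(n):
            out[s][cond] = SubjectParams(
                d_prime=float(d[s]),
                c1=float(scenario.c1[cond] + eps_c1[s]),
                c2_minus=float(scenario.c2_minus[cond] + dlt_m[s]),
                c2_plus=float(scenario.c2_plus[cond] + dlt_p[s]),
                m_ratio=float(meta_d[s] / d[s]),
            )
    return out


def _joint_cells(params: SubjectParams, anchor: str) -> np.ndarray:
    """P(resp, conf | stim): Type-1 response probabilities from (d', c1)
    composed with meta-level confidence conditionals."""
    type1 = response_probabilities_type1(params.d_prime, params.c1)
    cond = cell_probabilities(params, anchor=anchor).conditional
    return type1[:, :, None] * cond


def simulate_counts(params: SubjectParams, n_trials: int = 96,
                    prevalence: float = 0.5, mode: str = "expected",
                    rng: np.random.Generator | None = None,
                    anchor: str = "meta") -> ConfidenceCounts:
    """Confidence-count table for one subject x condition.

    ``mode="expected"`` returns the continuous expected counts
    ``n_trials x prevalence-weighted cell probabilities`` (the default:
    randomness then enters only through subject parameter draws);
    ``mode="multinomial"`` draws integer counts per stimulus class.
    The stimulus split is exact: round(n_trials * prevalence) present
    trials, the rest absent.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie strictly between 0 and 1")
    cells = _joint_cells(params, anchor)
    n_present = int(round(n_trials * prevalence))
    n_stim = np.array([n_trials - n_present, n_present], dtype=float)

    if mode == "expected":
        counts = n_stim[:, None, None] * cells
    elif mode == "multinomial":
        if rng is None:
            raise ValueError("multinomial mode requires an rng")
        counts = np.empty((2, 2, 2))
        for i in range(2):
            p = cells[i].ravel()
            counts[i] = rng.multinomial(int(n_stim[i]), p / p.sum()).reshape(2, 2)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'expected' or 'multinomial'")
    return ConfidenceCounts(counts)


def summarize_mean_confidence(counts: ConfidenceCounts) -> dict:
    """High-confidence proportion per response class.

    For "absent" responses: (high CRs + high misses) / (CRs + misses);
    for "present" responses: (high hits + high FAs) / (hits + FAs).
    A response class with zero trials yields NaN (the undefined flag).
    """
    c = counts.counts
    out = {}
    for j, name in enumerate(("absent", "present")):
        total = c[:, j, :].sum()
        out[name] = float(c[:, j, 1].sum() / total) if total > 0 else float("nan")
    return out


@dataclass(frozen=True)
class TrialDesign:
    """Block structure and confidence-scale mapping for trial synthesis."""

    n_blocks: int = 4
    trials_per_block: int = 24
    prevalence: float = 0.5
    confidence_center: float = 50.0
    confidence_spread: tuple = (5.0, 30.0)   # |offset| range from the center
    rt_median_ms: float = 700.0
    rt_sigma: float = 0.35
    high_conf_rt_factor: float = 0.85        # high confidence -> faster
    imagery_check_pass_prob: float = 1.0

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


def _confidence_from_bins(bins: np.ndarray, design: TrialDesign,
                          rng: np.random.Generator) -> np.ndarray:
    """Continuous ratings whose within-group z-split recovers ``bins``.

    Low trials sit below the center, high trials above, with the smaller
    side's offsets shrunk so the sample mean equals the center exactly;
    the z-score boundary then separates the bins by construction.  An
    all-low group degenerates to constant ratings (zero-variance flag
    downstream, still all-low).  An all-high group has no continuous
    representation under a mean split and also degenerates to constants.
    """
    lo, hi = design.confidence_spread
    n = bins.size
    off = rng.uniform(lo, hi, size=n)
    signed = np.where(bins > 0, off, -off)
    pos, neg = signed[bins > 0].sum(), -signed[bins == 0].sum()
    if pos == 0.0 or neg == 0.0:
        return np.full(n, design.confidence_center)
    if pos > neg:
        signed[bins > 0] *= neg / pos
    else:
        signed[bins == 0] *= pos / neg
    return design.confidence_center + signed


def simulate_trials(params: SubjectParams, design: TrialDesign,
                    rng: np.random.Generator, subject_id: str = "s01",
                    condition: str = IMAGERY, anchor: str = "meta",
                    counts: ConfidenceCounts | None = None) -> pd.DataFrame:
    """Trial-level records for one subject x condition.

    Counts are drawn multinomially from the subject's cell probabilities
    (or taken from ``counts`` if given), expanded to trials, shuffled and
    laid out over blocks; continuous confidence ratings are constructed
    so that re-binarization (z-split) and re-tabulation recover the
    generating count table.  Reaction times are log-normal with faster
    high-confidence responses.
    """
    if counts is None:
        counts = simulate_counts(params, n_trials=design.n_trials,
                                 prevalence=design.prevalence,
                                 mode="multinomial", rng=rng, anchor=anchor)
    if counts.total != design.n_trials:
        raise ValueError("count table total does not match the design")
    stim, resp, conf = [], [], []
    for i in range(2):
        for j in range(2):
            for y in range(2):
                k = int(counts.counts[i, j, y])
                stim += [i] * k
                resp += [j] * k
                conf += [y] * k
    order = rng.permutation(design.n_trials)
    stim = np.asarray(stim)[order]
    resp = np.asarray(resp)[order]
    conf_bin = np.asarray(conf)[order]

    confidence = _confidence_from_bins(conf_bin, design, rng)
    rt = design.rt_median_ms * np.exp(rng.normal(0.0, design.rt_sigma,
                                                 size=design.n_trials))
    rt *= np.where(conf_bin > 0, design.high_conf_rt_factor, 1.0)

    blocks = np.repeat(np.arange(design.n_blocks), design.trials_per_block)
    check = (rng.uniform(size=design.n_blocks)
             < design.imagery_check_pass_prob).astype(int)
    return pd.DataFrame({
        "subject_id": subject_id,
        "condition": condition,
        "block": blocks,
        "stimulus": stim,
        "response": resp,
        "confidence": np.round(confidence, 4),
        "rt_ms": np.round(rt, 1),
        "imagery_check_pass": check[blocks],
    })


@dataclass
class SimulatedCohort:
    """One simulated study: subject truths plus per-condition count tables."""

    scenario: GroupScenario
    seed: int | None
    subjects: list                       # list of {condition: SubjectParams}
    counts: dict = field(default_factory=dict)  # condition -> list[ConfidenceCounts]
    mode: str = "expected"

    @property
    def conditions(self) -> tuple:
        return self.scenario.conditions

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def counts_frame(self) -> pd.DataFrame:
        """Long-format count table across subjects and conditions."""
        frames = []
        for cond in self.conditions:
            for s, table in enumerate(self.counts[cond]):
                frames.append(table.to_frame(subject_id=f"s{s:03d}", condition=cond))
        return pd.concat(frames, ignore_index=True)


def simulate_cohort(scenario: GroupScenario, seed=None,
                    mode: str = "expected", anchor: str = "meta",
                    rng: np.random.Generator | None = None) -> SimulatedCohort:
    """Sample a cohort and tabulate counts for every subject x condition."""
    if rng is None:
        rng = np.random.default_rng(seed)
    subjects = sample_subjects(scenario, rng)
    counts: dict = {cond: [] for cond in scenario.conditions}
    for subj in subjects:
        for cond in scenario.conditions:
            counts[cond].append(
                simulate_counts(subj[cond], n_trials=scenario.n_trials_per_condition,
                                mode=mode, rng=rng, anchor=anchor)
            )
    return SimulatedCohort(scenario=scenario, seed=seed, subjects=subjects,
                           counts=counts, mode=mode)


def cohort_trials(scenario: GroupScenario, design: TrialDesign | None = None,
                  seed=None, anchor: str = "meta",
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Trial-level table for a whole cohort (one row per trial)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if design is None:
        design = TrialDesign()
    subjects = sample_subjects(scenario, rng)
    frames = []
    for s, subj in enumerate(subjects):
        for cond in scenario.conditions:
            frames.append(
                simulate_trials(subj[cond], design, rng,
                                subject_id=f"s{s:03d}", condition=cond,
                                anchor=anchor)
            )
    return pd.concat(frames, ignore_index=True)
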