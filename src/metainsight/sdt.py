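"""First-order signal detection estimation and confidence binarization.

Implements the equal-variance Gaussian SDT estimators

    d' = z(H) - z(FA)        c = -0.5 * (z(H) + z(FA))

where ``z`` is the inverse standard-normal CDF, ``H`` the hit rate and
``FA`` the false-alarm rate, together with the 0.5-count correction for
extreme cells (H = 1 or 0, FA = 0 or 1), the within-(subject, condition)
z-score split of continuous confidence ratings into low/high bins, and the
tabulation of trials into the 2 (stimulus) x 2 (response) x 2 (confidence
bin) count tables that the Type-2 model treats as its likelihood unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

__all__ = [
    "DetectionCounts",
    "SDTEstimate",
    "BinnedConfidence",
    "ConfidenceCounts",
    "estimate_type1",
    "zscore_split",
    "tabulate_counts",
]

#: axis order of a confidence-count table: [stimulus, response, bin]
#: with 0 = absent/low and 1 = present/high on every axis.
COUNT_AXES = ("stimulus", "response", "conf_bin")


@dataclass(frozen=True)
class DetectionCounts:
    """Trial counts of the four Type-1 outcome classes.

    Counts may be non-integer (e.g. expected counts from a generative
    model); they must be non-negative.
    """

    n_hit: float
    n_miss: float
    n_fa: float
    n_cr: float

    def __post_init__(self) -> None:
        for name in ("n_hit", "n_miss", "n_fa", "n_cr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_signal(self) -> float:
        return self.n_hit + self.n_miss

    @property
    def n_noise(self) -> float:
        return self.n_fa + self.n_cr


@dataclass(frozen=True)
class SDTEstimate:
    """First-order sensitivity and bias for one subject x condition."""

    d_prime: float
    criterion: float
    hit_rate: float
    fa_rate: float
    correction_applied: bool = False


@dataclass(frozen=True)
class BinnedConfidence:
    """Binary low/high labels for one subject x condition.

    ``labels`` holds 0 (low) / 1 (high) per trial, in input order.
    ``zero_variance`` flags a degenerate all-identical rating vector, in
    which case every trial is labelled low; such subjects are normally
    removed upstream by the confidence-invariance exclusion rule.
    """

    labels: np.ndarray
    zero_variance: bool = False


@dataclass
class ConfidenceCounts:
    """2 x 2 x 2 table of trial counts: [stimulus, response, bin].

    Index 0 = absent/low, 1 = present/high on every axis.  This is the
    likelihood unit of the Type-2 model: counts per confidence bin
    conditional on stimulus category and response.
    """

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((2, 2, 2), dtype=float)
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, 2, 2):
            raise ValueError("counts must have shape (2, 2, 2)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def per_stimulus(self) -> np.ndarray:
        """Trial totals per stimulus class (absent, present)."""
        return self.counts.sum(axis=(1, 2))

    def detection_counts(self) -> DetectionCounts:
        """Collapse over confidence bins to Type-1 outcome counts."""
        c = self.counts
        return DetectionCounts(
            n_hit=float(c[1, 1].sum()),
            n_miss=float(c[1, 0].sum()),
            n_fa=float(c[0, 1].sum()),
            n_cr=float(c[0, 0].sum()),
        )

    def to_frame(self, **keys: object) -> pd.DataFrame:
        """Long-format table with one row per cell, plus constant key columns."""
        rows = []
        for i in range(2):
            for j in range(2):
                for y in range(2):
                    rows.append(
                        {**keys, "stim": i, "resp": j, "conf_bin": y,
                         "count": self.counts[i, j, y]}
                    )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConfidenceCounts":
        counts = np.zeros((2, 2, 2))
        for _, row in frame.iterrows():
            counts[int(row["stim"]), int(row["resp"]), int(row["conf_bin"])] += row["count"]
        return cls(counts)


def estimate_type1(counts: DetectionCounts) -> SDTEstimate:
    """Estimate d' and criterion c from Type-1 outcome counts.

    Hit rates of 1 (or 0) and false-alarm rates of 0 (or 1) bias the
    z-transform; in those cases a count of 0.5 is added to (or subtracted
    from) the offending cell only, i.e. H = 1 becomes (n - 0.5)/n and
    FA = 0 becomes 0.5/n, and ``correction_applied`` is set.

    Raises
    ------
    ValueError
        If either stimulus class has zero trials (non-estimable).
    """
    n_sig, n_noise = counts.n_signal, counts.n_noise
    if n_sig <= 0 or n_noise <= 0:
        raise ValueError(
            "cannot estimate d'/c with zero trials in a stimulus class "
            f"(n_signal={n_sig}, n_noise={n_noise})"
        )

    hit, fa = counts.n_hit, counts.n_fa
    corrected = False
    if hit == 0:
        hit, corrected = 0.5, True
    elif hit == n_sig:
        hit, corrected = n_sig - 0.5, True
    if fa == 0:
        fa, corrected = 0.5, True
    elif fa == n_noise:
        fa, corrected = n_noise - 0.5, True

    H = hit / n_sig
    FA = fa / n_noise
    zH, zFA = ndtri(H), ndtri(FA)
    return SDTEstimate(
        d_prime=float(zH - zFA),
        criterion=float(-0.5 * (zH + zFA)),
        hit_rate=float(H),
        fa_rate=float(FA),
        correction_applied=corrected,
    )


def zscore_split(ratings, ddof: int = 1) -> BinnedConfidence:
    """Split one subject x condition's confidence ratings at their z-score.

    A rating is labelled high iff its z-score (computed with the group's
    own mean and standard deviation) is strictly above 0; ties at z = 0
    and all ratings below are labelled low.  ``ddof=1`` uses the sample
    standard deviation (the default); the choice does not affect labels,
    only the scale of the z-scores.

    Zero-variance inputs yield all-low labels with ``zero_variance`` set
    rather than an error: the exclusion pipeline is the designated
    remover of such subjects.
    """
    x = np.asarray(ratings, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 ratings to z-score")
    sd = x.std(ddof=ddof)
    # relative guard: spacing-level spread is zero variance, not signal
    if not np.isfinite(sd) or sd <= 1e-9 * max(1.0, float(np.abs(x).max())):
        return BinnedConfidence(labels=np.zeros(x.size, dtype=int),
                                zero_variance=True)
    z = (x - x.mean()) / sd
    return BinnedConfidence(labels=(z > 0).astype(int), zero_variance=False)


def tabulate_counts(trials: pd.DataFrame) -> ConfidenceCounts:
    """Tabulate binned trials into a 2 x 2 x 2 confidence-count table.

    ``trials`` must carry integer columns ``stimulus``, ``response`` and
    ``conf_bin`` (each coded 0/1).  Empty cells are allowed; marginal sums
    equal the number of input rows.
    """
    for col in ("stimulus", "response", "conf_bin"):
        if col not in trials.columns:
            raise ValueError(f"trials table lacks required column '{col}'")
    counts = np.zeros((2, 2, 2))
    stim = trials["stimulus"].to_numpy(dtype=int)
    resp = trials["response"].to_numpy(dtype=int)
    conf = trials["conf_bin"].to_numpy(dtype=int)
    np.add.at(counts, (stim, resp, conf), 1.0)
    return ConfidenceCounts(counts)


def binarize_trials(trials: pd.DataFrame, ddof: int = 1,
                    warn_zero_variance: bool = True) -> pd.DataFrame:
    """Attach a ``conf_bin`` column via per-(subject, condition) z-splits.

    Returns a copy of ``trials`` with the new column; emits a warning for
    zero-variance groups (which get all-low labels).
    """
    out = trials.copy()
    out["conf_bin"] = 0
    for (subj, cond), idx in out.groupby(["subject_id", "condition"]).groups.items():
        binned = zscore_split(out.loc[idx, "confidence"].to_numpy(), ddof=ddof)
        out.loc[idx, "conf_bin"] = binned.labels
        if binned.zero_variance and warn_zero_variance:
            warnings.warn(
                f"zero confidence variance for subject {subj!r}, "
                f"condition {cond!r}: all trials labelled low",
                stacklevel=2,
            )
    return out
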