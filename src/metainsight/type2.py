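"""Closed-form Type-2 signal detection probabilities.

The meta-d' framework evaluates confidence against a *meta-level*
equal-variance SDT model: evidence x ~ N(-meta-d'/2, 1) when the stimulus
is absent and N(+meta-d'/2, 1) when present.  The Type-1 split falls at the
meta-level criterion c1', and confidence criteria sit at signed distances
from the decision criterion: a "present" response is rated high confidence
iff x > c2+, an "absent" response iff x < c2-.

Two anchoring conventions for c1' are supported:

* ``"meta"`` (default, the meta-d' convention): c1' = c1 * meta-d'/d'
  (= c1 * M-ratio), which preserves the *relative* criterion under the
  change of sensitivity, with the criterion distances dc2 = c2 - c1
  applied around c1' in meta space;
* ``"empirical_c1"``: c1' = c1, criteria used as given.

This module is shared by the cohort simulator and by the hierarchical
model's multinomial likelihood, which consumes the conditionals
P(conf = y | stim = i, resp = j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = [
    "SubjectParams",
    "CellProbabilities",
    "meta_d_from_mratio",
    "cell_probabilities",
    "response_probabilities_type1",
    "conditional_high_probs",
]

#: response probabilities below this make P(conf | stim, resp) undefined;
#: the conditional is then reported as 0.5/0.5 and flagged.
DEGENERATE_EPS = 1e-12

ANCHORS = ("meta", "empirical_c1")


@dataclass(frozen=True)
class SubjectParams:
    """Generative truth for one subject (evidence-axis units).

    ``c2_minus < c1 < c2_plus`` must hold; ``d_prime`` and ``m_ratio``
    must be positive for a proper Type-2 model (boundary values are
    tolerated by :func:`cell_probabilities` for limiting cases).
    """

    d_prime: float
    c1: float
    c2_minus: float
    c2_plus: float
    m_ratio: float

    def __post_init__(self) -> None:
        if not (self.c2_minus < self.c1 < self.c2_plus):
            raise ValueError(
                "confidence criteria must satisfy c2_minus < c1 < c2_plus, "
                f"got {self.c2_minus} / {self.c1} / {self.c2_plus}"
            )
        if self.d_prime < 0:
            raise ValueError("d_prime must be non-negative")
        if self.m_ratio < 0:
            raise ValueError("m_ratio must be non-negative")

    @property
    def meta_d(self) -> float:
        return self.m_ratio * self.d_prime

    @property
    def dc2_minus(self) -> float:
        """Signed distance of the negative confidence criterion from c1."""
        return self.c2_minus - self.c1

    @property
    def dc2_plus(self) -> float:
        """Signed distance of the positive confidence criterion from c1."""
        return self.c2_plus - self.c1


@dataclass(frozen=True)
class CellProbabilities:
    """Joint and conditional Type-2 cell probabilities.

    Arrays are indexed [stimulus, response, bin] with 0 = absent/low and
    1 = present/high.  ``joint[i, j, y]`` is P(resp = j, conf = y | stim = i)
    under the meta-level model; ``conditional[i, j, y]`` is
    P(conf = y | stim = i, resp = j); ``resp_given_stim[i, j]`` is the
    meta-level P(resp = j | stim = i).  ``degenerate`` flags (stim, resp)
    pairs whose response probability fell below the numerical guard, for
    which the conditional is reported as 0.5/0.5.
    """

    joint: np.ndarray
    conditional: np.ndarray
    resp_given_stim: np.ndarray
    degenerate: bool = False


def meta_d_from_mratio(d_prime: float, m_ratio: float) -> float:
    """meta-d' = M-ratio x d'; requires a positive d'."""
    if d_prime <= 0:
        raise ValueError("d_prime must be positive")
    return m_ratio * d_prime


def _meta_criteria(meta_d, m_ratio, c1, dc2_minus, dc2_plus, anchor):
    """Effective meta-level criteria (c1', theta-, theta+)."""
    if anchor not in ANCHORS:
        raise ValueError(f"unknown anchor {anchor!r}; expected one of {ANCHORS}")
    c1p = c1 * m_ratio if anchor == "meta" else c1
    return c1p, c1p + dc2_minus, c1p + dc2_plus


def cell_probabilities(params: SubjectParams, anchor: str = "meta") -> CellProbabilities:
    """Meta-level joint and conditional cell probabilities for one subject.

    Evidence means sit at -meta-d'/2 (stimulus absent) and +meta-d'/2
    (present); the Type-1 split falls at the anchored criterion c1' and
    high confidence requires evidence beyond c2+ ("present" responses) or
    below c2- ("absent" responses).
    """
    meta_d = params.meta_d
    c1p, th_m, th_p = _meta_criteria(
        meta_d, params.m_ratio, params.c1, params.dc2_minus, params.dc2_plus, anchor
    )
    joint = np.empty((2, 2, 2))
    for i, mu in enumerate((-meta_d / 2.0, +meta_d / 2.0)):
        p_high_present = ndtr(mu - th_p)          # x > theta+
        p_present = ndtr(mu - c1p)                # x > c1'
        p_high_absent = ndtr(th_m - mu)           # x < theta-
        p_absent = ndtr(c1p - mu)                 # x < c1'
        joint[i, 1, 1] = p_high_present
        joint[i, 1, 0] = p_present - p_high_present
        joint[i, 0, 1] = p_high_absent
        joint[i, 0, 0] = p_absent - p_high_absent
    joint = np.clip(joint, 0.0, 1.0)

    resp = joint.sum(axis=2)
    conditional = np.empty_like(joint)
    degenerate = False
    for i in range(2):
        for j in range(2):
            if resp[i, j] < DEGENERATE_EPS:
                conditional[i, j] = 0.5
                degenerate = True
            else:
                conditional[i, j] = joint[i, j] / resp[i, j]
    return CellProbabilities(
        joint=joint, conditional=conditional, resp_given_stim=resp,
        degenerate=degenerate,
    )


def response_probabilities_type1(d_prime: float, c1: float) -> np.ndarray:
    """Type-1 response probabilities P(resp = j | stim = i).

    First-order equal-variance SDT with evidence means at -d'/2 / +d'/2
    and the decision criterion at c1.  Returns a (2, 2) array indexed
    [stimulus, response].
    """
    out = np.empty((2, 2))
    for i, mu in enumerate((-d_prime / 2.0, +d_prime / 2.0)):
        p_present = ndtr(mu - c1)
        out[i, 1] = p_present
        out[i, 0] = 1.0 - p_present
    return out


def conditional_high_probs(meta_d, c1, dc2_minus, dc2_plus, m_ratio=None,
                           anchor: str = "meta"):
    """Vectorized P(conf = high | stim, resp) for the model likelihood.

    All parameter arguments broadcast together.  Returns
    ``(p_high_given_present_resp, p_high_given_absent_resp)``, each of
    shape ``broadcast_shape + (2,)`` with the trailing axis indexing the
    stimulus (0 = absent, 1 = present).  Response probabilities below the
    numerical guard yield a conditional of 0.5.

    ``m_ratio`` is required for the ``"meta"`` anchor (where
    c1' = c1 * M); it is ignored for ``"empirical_c1"``.
    """
    meta_d = np.asarray(meta_d, dtype=float)
    if anchor == "meta":
        if m_ratio is None:
            raise ValueError("m_ratio is required for the 'meta' anchor")
        c1p = np.asarray(c1, dtype=float) * np.asarray(m_ratio, dtype=float)
    elif anchor == "empirical_c1":
        c1p = np.asarray(c1, dtype=float) + 0.0 * meta_d
    else:
        raise ValueError(f"unknown anchor {anchor!r}; expected one of {ANCHORS}")
    th_m = c1p + np.asarray(dc2_minus)
    th_p = c1p + np.asarray(dc2_plus)

    mu = np.stack(np.broadcast_arrays(-meta_d / 2.0, +meta_d / 2.0), axis=-1)
    c1p = np.asarray(c1p)[..., None]
    th_m = np.asarray(th_m)[..., None]
    th_p = np.asarray(th_p)[..., None]

    p_present = ndtr(mu - c1p)
    p_absent = 1.0 - p_present
    p_high_pres = np.where(
        p_present < DEGENERATE_EPS, 0.5,
        ndtr(mu - th_p) / np.maximum(p_present, DEGENERATE_EPS),
    )
    p_high_abs = np.where(
        p_absent < DEGENERATE_EPS, 0.5,
        ndtr(th_m - mu) / np.maximum(p_absent, DEGENERATE_EPS),
    )
    # conditionals are probabilities; clip away rounding excursions
    return np.clip(p_high_pres, 0.0, 1.0), np.clip(p_high_abs, 0.0, 1.0)
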