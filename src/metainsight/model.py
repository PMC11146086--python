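"""Hierarchical Bayesian meta-d' model with asymmetric confidence-criterion priors.

The model estimates, per condition t, group distributions of three
subject-level quantities: the log M-ratio (meta-d'/d'), and the signed
distances of the negative and positive confidence criteria from the
decision criterion, dc2- = c2- - c1 (< 0) and dc2+ = c2+ - c1 (> 0).
Type-1 d' and c1 enter as fixed per-subject point estimates; the
likelihood is a per-(stimulus, response) multinomial over confidence bins
with cell probabilities from :mod:`metainsight.type2`.

Structure (condition index t, subject index s):

    log M_st   ~ Normal(mu_logM_t, (xi_M * sigma~_M_t)^2)
    dc2-_st    ~ Normal(mu_dc2-_t, sigma_dc2-_t^2) truncated to (-inf, 0)
    dc2+_st    ~ Normal(mu_dc2+_t, sigma_dc2+_t^2) truncated to (0, inf)

with hyperpriors following the toolbox defaults of the JAGS lineage this
model extends: Normal(0, 0.5^2) on mu_logM, a vague Normal(0, 10^2) on
the dc2 group locations and a scale-invariant (log-uniform) prior on the
dc2 group scales (an informative location prior would pull the weakly
identified truncated-normal location/scale pair along its ridge toward
zero; a half-Normal scale option is provided), half-Normal(1) on the
logM group scale, and the redundant
multiplicative parameter xi_M ~ Beta(1, 1) scaling the
log-M hierarchy (Matzke-style parameter expansion; the reported
sigma_logM is xi_M * sigma~_M).  Truncation enforces the criterion
ordering dc2- < 0 < dc2+ by construction.

The *standard* (symmetric) variant shares one group prior over the
magnitudes |dc2-| and dc2+ per condition — the original formulation in
which confidence criteria are modelled symmetrically around c1 — and is
used to estimate per-condition metacognitive efficiency M.

Inference runs a Metropolis-within-Gibbs sampler, vectorized over
subjects (subject blocks are conditionally independent given the group
level, so all subjects are updated in parallel with warmup-adapted
random-walk proposals).  Group-level scalars are updated by gridded
independence-Metropolis draws from their conditionals, which depend on
the subject values only through sufficient statistics; the group mean of
log M is a conjugate Gibbs update; sigma_logM is sampled non-centered
(conditioning on the standardized subject deviations) to traverse the
hierarchical funnel; and two joint expansion moves (a location shift of
the whole log-M hierarchy, and a scale move multiplying meta-d' together
with all criterion distances — the posterior's near-flat direction)
decorrelate the levels.  Conditions are fitted jointly with
condition-indexed group priors, so between-condition contrasts are
per-draw differences.  Diagnostics (R-hat, bulk ESS) come from arviz.

The headline statistic is the posterior asymmetry

    A_t = mu_dc2+_t - |mu_dc2-_t|

which is ~0 when confidence criteria track the decision criterion (no
insight) and positive when they stay anchored despite a criterion shift
(insight).  A is invariant to a shared shift of both criteria, which
makes it robust to the c1-anchoring convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr

from .sdt import estimate_type1
from .type2 import ANCHORS, conditional_high_probs

__all__ = [
    "ModelSpec",
    "SamplerConfig",
    "CohortData",
    "PosteriorSummary",
    "DiagnosticsReport",
    "fit_insight_model",
    "fit_standard_mratio",
    "hdi",
    "asymmetry_posterior",
    "condition_difference",
    "convergence_check",
    "fit_subject_mle",
]

_EPS = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """Hyperpriors and structural switches of the hierarchical model."""

    mu_logM_sd: float = 0.5        # Normal(0, sd^2) hyperprior on mu_logM_t
    mu_dc2_sd: float = 10.0        # Normal(0, sd^2) hyperprior on dc2 group means
    sigma_scale: float = 1.0       # half-Normal(scale) on the logM group sigma
    dc2_scale_prior: str = "log_uniform"  # prior on the dc2 group sigmas
    anchor: str = "meta"           # c1' convention, see metainsight.type2
    symmetric_c2: bool = False     # True -> shared |dc2| prior (standard model)

    def __post_init__(self) -> None:
        if self.anchor not in ANCHORS:
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if self.dc2_scale_prior not in ("log_uniform", "half_normal"):
            raise ValueError(
                f"unknown dc2_scale_prior {self.dc2_scale_prior!r}")
        for name in ("mu_logM_sd", "mu_dc2_sd", "sigma_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings.  Defaults: 4 chains, 1000 warmup + 1000 kept draws."""

    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    subject_sweeps: int = 2        # subject-block updates per iteration
    group_sweeps: int = 1          # group-scalar sweeps per iteration
    expansion_sweeps: int = 2      # joint location/scale moves per iteration
    seed: int | None = None
    store_subject_draws: bool = True
    target_accept_subject: float = 0.30
    target_accept_scalar: float = 0.44

    def __post_init__(self) -> None:
        if self.chains < 1 or self.draws < 1 or self.warmup < 0:
            raise ValueError("invalid sampler sizes")


@dataclass
class CohortData:
    """Per-subject count tables plus fixed Type-1 point estimates.

    ``counts[cond]`` has shape (S, 2, 2, 2) ([stim, resp, bin]);
    ``d_prime[cond]`` and ``c1[cond]`` are length-S arrays held constant
    during inference.
    """

    conditions: tuple
    subject_ids: list
    counts: dict
    d_prime: dict
    c1: dict

    def __post_init__(self) -> None:
        S = len(self.subject_ids)
        if S < 2:
            raise ValueError("need at least 2 subjects")
        for cond in self.conditions:
            c = np.asarray(self.counts[cond], dtype=float)
            if c.shape != (S, 2, 2, 2):
                raise ValueError(
                    f"counts for {cond!r} must have shape (S, 2, 2, 2)")
            if np.any(c < 0):
                raise ValueError("counts must be non-negative")
            self.counts[cond] = c
            for name in ("d_prime", "c1"):
                arr = np.asarray(getattr(self, name)[cond], dtype=float)
                if arr.shape != (S,):
                    raise ValueError(f"{name} for {cond!r} must be length S")
                getattr(self, name)[cond] = arr
            if np.any(self.d_prime[cond] <= 0):
                warnings.warn(
                    f"non-positive Type-1 d' in condition {cond!r}; "
                    "clipped to 0.01 for the meta-level anchor",
                    stacklevel=2,
                )
                self.d_prime[cond] = np.maximum(self.d_prime[cond], 0.01)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @classmethod
    def from_cohort(cls, cohort) -> "CohortData":
        """Build from a :class:`~metainsight.simulate.SimulatedCohort`,
        estimating Type-1 d'/c1 from each subject's own count table."""
        conditions = tuple(cohort.conditions)
        S = cohort.n_subjects
        counts, d1, c1 = {}, {}, {}
        for cond in conditions:
            counts[cond] = np.stack(
                [cohort.counts[cond][s].counts for s in range(S)])
            est = [estimate_type1(cohort.counts[cond][s].detection_counts())
                   for s in range(S)]
            d1[cond] = np.array([e.d_prime for e in est])
            c1[cond] = np.array([e.criterion for e in est])
        return cls(conditions=conditions,
                   subject_ids=[f"s{s:03d}" for s in range(S)],
                   counts=counts, d_prime=d1, c1=c1)

    @classmethod
    def from_frames(cls, counts_df: pd.DataFrame,
                    type1_df: pd.DataFrame) -> "CohortData":
        """Build from long-format tables (see the CSV interfaces).

        ``counts_df``: subject_id, condition, stim, resp, conf_bin, count.
        ``type1_df``: subject_id, condition, d_prime, criterion.
        """
        conditions = tuple(pd.unique(counts_df["condition"]))
        subject_ids = list(pd.unique(counts_df["subject_id"]))
        idx = {s: k for k, s in enumerate(subject_ids)}
        S = len(subject_ids)
        counts = {cond: np.zeros((S, 2, 2, 2)) for cond in conditions}
        for _, row in counts_df.iterrows():
            counts[row["condition"]][
                idx[row["subject_id"]], int(row["stim"]), int(row["resp"]),
                int(row["conf_bin"])] += row["count"]
        d1 = {cond: np.full(S, np.nan) for cond in conditions}
        c1 = {cond: np.full(S, np.nan) for cond in conditions}
        for _, row in type1_df.iterrows():
            cond, s = row["condition"], idx[row["subject_id"]]
            d1[cond][s] = row["d_prime"]
            c1[cond][s] = row["criterion"]
        for cond in conditions:
            if np.isnan(d1[cond]).any() or np.isnan(c1[cond]).any():
                raise ValueError(f"missing Type-1 estimates for {cond!r}")
        return cls(conditions=conditions, subject_ids=subject_ids,
                   counts=counts, d_prime=d1, c1=c1)


# --------------------------------------------------------------------------
# log-density building blocks (additive constants dropped throughout)

def _loglik(logM, dm, dp, d1, c1, counts, anchor):
    """Multinomial log-likelihood per (condition, subject).

    ``logM, dm, dp, d1, c1``: arrays (T, S); ``counts``: (T, S, 2, 2, 2).
    Uses the response-conditional bin probabilities only, as in the
    meta-d' framework (Type-1 response totals carry no information about
    the meta level once d'/c1 are fixed).
    """
    M = np.exp(logM)
    php, pha = conditional_high_probs(M * d1, c1, dm, dp, m_ratio=M,
                                      anchor=anchor)
    php = np.clip(php, _EPS, 1.0 - _EPS)
    pha = np.clip(pha, _EPS, 1.0 - _EPS)
    # counts axes: [t, s, stim, resp, bin]; conditionals: [t, s, stim]
    c = np.moveaxis(counts, 2, -1)  # -> [t, s, resp, bin, stim]
    return (
        c[:, :, 1, 1] * np.log(php) + c[:, :, 1, 0] * np.log1p(-php)
        + c[:, :, 0, 1] * np.log(pha) + c[:, :, 0, 0] * np.log1p(-pha)
    ).sum(axis=-1)


def _norm_logpdf(x, mu, sigma):
    return -np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


def _tn_neg_logpdf(x, mu, sigma):
    """Normal(mu, sigma^2) truncated to (-inf, 0); -inf for x >= 0."""
    out = _norm_logpdf(x, mu, sigma) - log_ndtr(-mu / sigma)
    return np.where(x < 0, out, -np.inf)


def _tn_pos_logpdf(x, mu, sigma):
    """Normal(mu, sigma^2) truncated to (0, inf); -inf for x <= 0."""
    out = _norm_logpdf(x, mu, sigma) - log_ndtr(mu / sigma)
    return np.where(x > 0, out, -np.inf)


def _subject_prior(logM, dm, dp, g, spec):
    """Subject-level prior log density (T, S) given group state ``g``."""
    sig_M = g["xi"] * g["sig_t_M"]
    lp = _norm_logpdf(logM, g["mu_logM"][:, None], sig_M[:, None])
    if spec.symmetric_c2:
        lp = lp + _tn_neg_logpdf(dm, -g["mu_c2"][:, None], g["sig_c2"][:, None])
        lp = lp + _tn_pos_logpdf(dp, g["mu_c2"][:, None], g["sig_c2"][:, None])
    else:
        lp = lp + _tn_neg_logpdf(dm, g["mu_m"][:, None], g["sig_m"][:, None])
        lp = lp + _tn_pos_logpdf(dp, g["mu_p"][:, None], g["sig_p"][:, None])
    return lp


def _truncnorm_moments(loc, scale):
    """Mean and SD of Normal(loc, scale^2) truncated to (0, inf).

    Stable closed form via the standard-normal hazard; ``loc``/``scale``
    broadcast.  (For truncation to (-inf, 0), negate ``loc`` and the
    returned mean.)
    """
    loc = np.asarray(loc, dtype=float)
    scale = np.asarray(scale, dtype=float)
    a = loc / scale
    # hazard of the lower tail: phi(a) / Phi(a), clipped for far tails
    phi = np.exp(-0.5 * a ** 2) / np.sqrt(2.0 * np.pi)
    lam = phi / np.maximum(ndtr(a), _EPS)
    mean = loc + scale * lam
    var = scale ** 2 * (1.0 - lam * (lam + a))
    return mean, np.sqrt(np.maximum(var, 0.0))


# --------------------------------------------------------------------------
# per-subject maximum likelihood (initialization + shrinkage reference)

def fit_subject_mle(counts, d_prime, c1, anchor: str = "meta",
                    bounds=((-2.5, 1.5), (-5.0, -1e-3), (1e-3, 5.0))):
    """Maximum-likelihood (log M, dc2-, dc2+) for one subject x condition.

    ``counts`` is a (2, 2, 2) array.  Estimates are box-constrained to
    keep degenerate tables (empty response classes) finite.
    """
    counts = np.asarray(counts, dtype=float)[None, None]
    d1 = np.array([[d_prime]])
    c1a = np.array([[c1]])

    def nll(theta):
        lm, dm, dp = theta
        return -float(_loglik(np.array([[lm]]), np.array([[dm]]),
                              np.array([[dp]]), d1, c1a, counts, anchor)[0, 0])

    res = minimize(nll, x0=np.array([0.0, -0.7, 0.7]), method="L-BFGS-B",
                   bounds=bounds)
    return tuple(float(v) for v in res.x)


# --------------------------------------------------------------------------
# the sampler

def _init_state(mle, spec, rng, T, S):
    """Chain-specific initial state, jittered around the subject MLEs."""
    logM = mle["logM"] + rng.normal(0, 0.05, size=(T, S))
    dm = np.minimum(mle["dm"] + rng.normal(0, 0.05, size=(T, S)), -1e-3)
    dp = np.maximum(mle["dp"] + rng.normal(0, 0.05, size=(T, S)), 1e-3)
    g = {
        "mu_logM": logM.mean(axis=1) + rng.normal(0, 0.03, size=T),
        "sig_t_M": np.clip(logM.std(axis=1), 0.1, None) / 0.7
        * np.exp(rng.normal(0, 0.1, size=T)),
        "xi": float(np.clip(0.7 + rng.normal(0, 0.05), 0.05, 0.95)),
    }
    if spec.symmetric_c2:
        mag = np.concatenate([-dm, dp], axis=1)
        g["mu_c2"] = mag.mean(axis=1) + rng.normal(0, 0.03, size=T)
        g["sig_c2"] = np.clip(mag.std(axis=1), 0.1, None) \
            * np.exp(rng.normal(0, 0.1, size=T))
    else:
        g["mu_m"] = dm.mean(axis=1) + rng.normal(0, 0.03, size=T)
        g["sig_m"] = np.clip(dm.std(axis=1), 0.1, None) \
            * np.exp(rng.normal(0, 0.1, size=T))
        g["mu_p"] = dp.mean(axis=1) + rng.normal(0, 0.03, size=T)
        g["sig_p"] = np.clip(dp.std(axis=1), 0.1, None) \
            * np.exp(rng.normal(0, 0.1, size=T))
    return logM, dm, dp, g


def _grid_update(logdens_vec, x_cur, rng, lo, hi, n=300):
    """Gridded independence-Metropolis update of one scalar.

    ``logdens_vec`` maps an array of candidate values to conditional log
    densities (cheap via sufficient statistics).  A candidate is drawn
    from the normalized grid (piecewise-constant proposal, uniform jitter
    within a cell) and accepted with the exact Metropolis-Hastings
    ratio, so the discretization is a proposal approximation only, not a
    bias.  Grid bounds must not depend on the current value of the
    updated coordinate (they may depend on the conditioning state).
    """
    xs = np.linspace(lo, hi, n)
    ld = logdens_vec(xs)
    ld = ld - ld.max()
    w = np.exp(ld)
    w /= w.sum()
    dx = (hi - lo) / (n - 1)
    i = int(rng.choice(n, p=w))
    x_prop = float(np.clip(xs[i] + (rng.uniform() - 0.5) * dx, lo, hi))
    j = int(np.clip(np.round((x_cur - lo) / dx), 0, n - 1))
    if x_cur < lo - dx or x_cur > hi + dx:
        return x_prop  # re-enter the supported range
    lp = logdens_vec(np.array([x_prop, x_cur]))
    log_alpha = (lp[0] - lp[1]
                 + np.log(max(w[j], 1e-300)) - np.log(w[i]))
    return x_prop if np.log(rng.uniform()) < log_alpha else x_cur


def _run_chain(counts, d1, c1, spec, config, mle, seed):
    """One MCMC chain; see the module docstring for the update schedule."""
    T, S = d1.shape
    rng = np.random.default_rng(seed)
    logM, dm, dp, g = _init_state(mle, spec, rng, T, S)
    anchor = spec.anchor

    side_names = (["mu_c2", "sig_c2"] if spec.symmetric_c2
                  else ["mu_m", "sig_m", "mu_p", "sig_p"])
    subj_scale = np.full((T, S), 0.15)
    shift_scale = np.full(T, 0.1)
    meta_scale = np.full(T, 0.1)

    ll = _loglik(logM, dm, dp, d1, c1, counts, anchor)
    n_iter = config.warmup + config.draws
    kept = {name: np.empty((config.draws, T))
            for name in ["mu_logM", "sig_t_M"] + side_names}
    kept_xi = np.empty(config.draws)
    if config.store_subject_draws:
        kept_subj = {name: np.empty((config.draws, T, S), dtype=np.float32)
                     for name in ("logM", "dc2_minus", "dc2_plus")}

    # grid bounds for the scale updates (log scale)
    u_lo, u_hi = np.log(3e-3), np.log(3.0)
    gamma = 0.05  # adaptation rate during warmup

    def update_side(theta, u, y_sum, y_sumsq, n_sub, rng):
        """One side hierarchy: positive-truncated Normal(theta, e^2u) for
        the distance magnitudes y > 0; updates (theta, u) Gibbs-style via
        gridded conditionals."""
        ybar = y_sum / n_sub
        sig = np.exp(u)

        def f_theta(th):
            return ((2.0 * th * y_sum - n_sub * th ** 2) / (2.0 * sig ** 2)
                    - n_sub * log_ndtr(th / sig)
                    - 0.5 * (th / spec.mu_dc2_sd) ** 2)

        theta = _grid_update(f_theta, theta, rng,
                             min(ybar, 0.0) - 5.0, ybar + 2.5, n=450)

        def f_u(u_):
            s2 = np.exp(2.0 * u_)
            rss = y_sumsq - 2.0 * theta * y_sum + n_sub * theta ** 2
            # log-uniform scale prior is flat on u; half-normal adds the
            # Gaussian penalty plus the log-scale Jacobian
            prior = (0.0 if spec.dc2_scale_prior == "log_uniform"
                     else -0.5 * s2 / spec.sigma_scale ** 2 + u_)
            return (-n_sub * u_ - rss / (2.0 * s2)
                    - n_sub * log_ndtr(theta / np.exp(u_)) + prior)

        u = _grid_update(f_u, u, rng, u_lo, u_hi, n=300)
        return theta, u

    for it in range(n_iter):
        adapting = it < config.warmup

        # --- subject blocks (vectorized over T x S) ---
        for _ in range(config.subject_sweeps):
            prior = _subject_prior(logM, dm, dp, g, spec)
            prop_logM = logM + subj_scale * rng.standard_normal((T, S))
            prop_dm = dm + subj_scale * rng.standard_normal((T, S))
            prop_dp = dp + subj_scale * rng.standard_normal((T, S))
            ok = (prop_dm < 0) & (prop_dp > 0)
            prop_ll = np.where(
                ok,
                _loglik(prop_logM, np.minimum(prop_dm, -_EPS),
                        np.maximum(prop_dp, _EPS), d1, c1, counts, anchor),
                -np.inf,
            )
            prop_prior = _subject_prior(prop_logM, prop_dm, prop_dp, g, spec)
            log_alpha = (prop_ll + prop_prior) - (ll + prior)
            accept = np.log(rng.uniform(size=(T, S))) < log_alpha
            logM = np.where(accept, prop_logM, logM)
            dm = np.where(accept, prop_dm, dm)
            dp = np.where(accept, prop_dp, dp)
            ll = np.where(accept, prop_ll, ll)
            if adapting:
                subj_scale *= np.exp(
                    gamma * (accept.astype(float)
                             - config.target_accept_subject))
                subj_scale = np.clip(subj_scale, 1e-3, 2.0)

        # --- group level, given subject values ---
        for _ in range(config.group_sweeps):
            # conjugate Gibbs for mu_logM (normal likelihood, normal prior)
            sig2 = (g["xi"] * g["sig_t_M"]) ** 2
            prec = 1.0 / spec.mu_logM_sd ** 2 + S / sig2
            mean = (logM.sum(axis=1) / sig2) / prec
            g["mu_logM"] = mean + rng.standard_normal(T) / np.sqrt(prec)

            # sigma~_M_t sampled non-centered: condition on the
            # standardized subject deviations eta = (logM - mu)/(xi sig~)
            # so the conditional is 1-d with the likelihood evaluated on
            # a grid (the funnel's centered conditional would pin sig~ to
            # the current deviations and never traverse the funnel)
            for t in range(T):
                eta = (logM[t] - g["mu_logM"][t]) / (g["xi"]
                                                     * g["sig_t_M"][t])

                def f_u(u_, t=t, eta=eta):
                    sigs = np.exp(np.atleast_1d(u_))
                    cand = (g["mu_logM"][t]
                            + g["xi"] * sigs[:, None] * eta[None, :])
                    G = cand.shape[0]
                    cll = _loglik(
                        cand,
                        np.broadcast_to(dm[t], (G, S)),
                        np.broadcast_to(dp[t], (G, S)),
                        np.broadcast_to(d1[t], (G, S)),
                        np.broadcast_to(c1[t], (G, S)),
                        np.broadcast_to(counts[t], (G, S, 2, 2, 2)),
                        anchor,
                    ).sum(axis=1)
                    return (cll - 0.5 * sigs ** 2 / spec.sigma_scale ** 2
                            + np.log(sigs))

                u_new = _grid_update(f_u, np.log(g["sig_t_M"][t]), rng,
                                     np.log(5e-3), np.log(2.0), n=31)
                g["sig_t_M"][t] = np.exp(u_new)
                logM[t] = (g["mu_logM"][t]
                           + g["xi"] * g["sig_t_M"][t] * eta)
            ll = _loglik(logM, dm, dp, d1, c1, counts, anchor)

            # side hierarchies via gridded conditionals on (theta, log sig)
            # where theta is the location of the positive-magnitude
            # parameterization (theta = -loc for the negative side)
            for t in range(T):
                if spec.symmetric_c2:
                    y = np.concatenate([-dm[t], dp[t]])
                    th, u = update_side(
                        g["mu_c2"][t], np.log(g["sig_c2"][t]),
                        float(y.sum()), float((y ** 2).sum()), 2 * S, rng)
                    g["mu_c2"][t], g["sig_c2"][t] = th, np.exp(u)
                else:
                    y = -dm[t]
                    th, u = update_side(
                        -g["mu_m"][t], np.log(g["sig_m"][t]),
                        float(y.sum()), float((y ** 2).sum()), S, rng)
                    g["mu_m"][t], g["sig_m"][t] = -th, np.exp(u)
                    y = dp[t]
                    th, u = update_side(
                        g["mu_p"][t], np.log(g["sig_p"][t]),
                        float(y.sum()), float((y ** 2).sum()), S, rng)
                    g["mu_p"][t], g["sig_p"][t] = th, np.exp(u)

            # xi_M via gridded conditional (Beta(1,1) prior on (0,1))
            rss_t = ((logM - g["mu_logM"][:, None]) ** 2).sum(axis=1)
            wgt = rss_t / g["sig_t_M"] ** 2

            def f_xi(x):
                return -T * S * np.log(x) - wgt.sum() / (2.0 * x ** 2)

            g["xi"] = _grid_update(f_xi, g["xi"], rng, 0.02, 0.999, n=300)

        # --- joint expansion moves across levels ---
        for _ in range(config.expansion_sweeps):
            # location move: shift mu_logM_t and every logM_st together
            # (when sigma_logM shrinks, single-site updates freeze the
            # centre of the hierarchy; this lets it slide)
            eps = shift_scale * rng.standard_normal(T)
            prop_logM = logM + eps[:, None]
            prop_ll = _loglik(prop_logM, dm, dp, d1, c1, counts, anchor)
            prop_mu = g["mu_logM"] + eps
            d_hyper = -0.5 * ((prop_mu ** 2 - g["mu_logM"] ** 2)
                              / spec.mu_logM_sd ** 2)
            log_alpha = (prop_ll - ll).sum(axis=1) + d_hyper
            acc_t = np.log(rng.uniform(size=T)) < log_alpha
            logM = np.where(acc_t[:, None], prop_logM, logM)
            ll = np.where(acc_t[:, None], prop_ll, ll)
            g["mu_logM"] = np.where(acc_t, prop_mu, g["mu_logM"])
            if adapting:
                shift_scale = np.clip(
                    shift_scale * np.exp(
                        gamma * (acc_t.astype(float)
                                 - config.target_accept_scalar)),
                    1e-3, 2.0)

            # scale move of the whole meta level: the posterior has a
            # near-flat direction that scales meta-d' together with all
            # confidence criteria (every z-argument of the likelihood
            # multiplies by e^eps); propose exactly that scaling.  The
            # subject-prior z-scores and truncation normalizers are
            # invariant, leaving delta-loglik, the hyperprior changes and
            # a residual group-parameter Jacobian.
            eps = meta_scale * rng.standard_normal(T)
            k = np.exp(eps)
            prop_logM = logM + eps[:, None]
            prop_dm = dm * k[:, None]
            prop_dp = dp * k[:, None]
            prop_ll = _loglik(prop_logM, prop_dm, prop_dp, d1, c1, counts,
                              anchor)
            prop_mu = g["mu_logM"] + eps
            d_hyper = -0.5 * ((prop_mu ** 2 - g["mu_logM"] ** 2)
                              / spec.mu_logM_sd ** 2)
            if spec.symmetric_c2:
                side_locs, side_scales = ["mu_c2"], ["sig_c2"]
            else:
                side_locs, side_scales = ["mu_m", "mu_p"], ["sig_m", "sig_p"]
            for name in side_locs:
                d_hyper += -0.5 * ((g[name] * k) ** 2 - g[name] ** 2) \
                    / spec.mu_dc2_sd ** 2
            n_group = len(side_locs)
            if spec.dc2_scale_prior == "half_normal":
                # with a log-uniform scale prior the density change and
                # the Jacobian of the scale rescale cancel exactly
                for name in side_scales:
                    d_hyper += -0.5 * ((g[name] * k) ** 2 - g[name] ** 2) \
                        / spec.sigma_scale ** 2
                n_group += len(side_scales)
            log_alpha = ((prop_ll - ll).sum(axis=1) + n_group * eps
                         + d_hyper)
            acc_t = np.log(rng.uniform(size=T)) < log_alpha
            logM = np.where(acc_t[:, None], prop_logM, logM)
            dm = np.where(acc_t[:, None], prop_dm, dm)
            dp = np.where(acc_t[:, None], prop_dp, dp)
            ll = np.where(acc_t[:, None], prop_ll, ll)
            g["mu_logM"] = np.where(acc_t, prop_mu, g["mu_logM"])
            for name in side_locs + side_scales:
                g[name] = np.where(acc_t, g[name] * k, g[name])
            if adapting:
                meta_scale = np.clip(
                    meta_scale * np.exp(
                        gamma * (acc_t.astype(float)
                                 - config.target_accept_scalar)),
                    1e-3, 2.0)

        # --- record raw group state ---
        if not adapting:
            k_it = it - config.warmup
            kept["mu_logM"][k_it] = g["mu_logM"]
            kept["sig_t_M"][k_it] = g["sig_t_M"]
            for name in side_names:
                kept[name][k_it] = g[name]
            kept_xi[k_it] = g["xi"]
            if config.store_subject_draws:
                kept_subj["logM"][k_it] = logM
                kept_subj["dc2_minus"][k_it] = dm
                kept_subj["dc2_plus"][k_it] = dp

    out = {"group": kept, "xi": kept_xi}
    if config.store_subject_draws:
        out["subject"] = kept_subj
    return out


# --------------------------------------------------------------------------
# posterior containers and summaries

@dataclass
class PosteriorSummary:
    """Posterior draws, HDIs and diagnostics for one hierarchical fit.

    ``draws`` maps group-parameter names (e.g. ``"mu_dc2_plus_imagery"``)
    to (chains, draws) arrays; ``subject_draws`` maps per-subject names
    (e.g. ``"logM_imagery"``) to (chains, draws, S) arrays.
    """

    conditions: tuple
    subject_ids: list
    draws: dict
    subject_draws: dict
    spec: ModelSpec
    config: SamplerConfig
    seed: int | None
    hdi_mass: float = 0.95

    def flat(self, name: str) -> np.ndarray:
        """All post-warmup samples of a parameter, chains concatenated."""
        return np.asarray(self.draws[name]).reshape(-1)

    def hdi_of(self, name: str, mass: float | None = None) -> tuple:
        return hdi(self.flat(name), mass or self.hdi_mass)

    def mean_of(self, name: str) -> float:
        return float(self.flat(name).mean())

    def summary_frame(self) -> pd.DataFrame:
        """Parameter table: mean, HDI bounds, R-hat, bulk ESS."""
        diag = convergence_check(self)
        rows = []
        for name in self.draws:
            lo, hi = self.hdi_of(name)
            rows.append({
                "parameter": name,
                "mean": self.mean_of(name),
                "hdi_low": lo,
                "hdi_high": hi,
                "rhat": diag.table.loc[name, "rhat"]
                if name in diag.table.index else np.nan,
                "ess_bulk": diag.table.loc[name, "ess_bulk"]
                if name in diag.table.index else np.nan,
            })
        return pd.DataFrame(rows)

    def to_inferencedata(self):
        import arviz as az
        return az.from_dict(posterior={k: np.asarray(v)
                                       for k, v in self.draws.items()})


@dataclass
class DiagnosticsReport:
    """R-hat / ESS table plus an overall pass flag (R-hat < threshold)."""

    table: pd.DataFrame
    passed: bool
    message: str
    rhat_threshold: float = 1.05


def fit_insight_model(data: CohortData, spec: ModelSpec | None = None,
                      config: SamplerConfig | None = None,
                      seed: int | None = None) -> PosteriorSummary:
    """Fit the asymmetric-criterion (insight) hierarchical model.

    Emits a warning (without failing) if any group-level R-hat exceeds
    1.05; callers gate on :func:`convergence_check`.
    """
    spec = spec or ModelSpec()
    config = config or SamplerConfig()
    if seed is None:
        seed = config.seed
    T = len(data.conditions)
    S = data.n_subjects

    counts = np.stack([data.counts[c] for c in data.conditions])
    d1 = np.stack([data.d_prime[c] for c in data.conditions])
    c1 = np.stack([data.c1[c] for c in data.conditions])

    mle = {"logM": np.empty((T, S)), "dm": np.empty((T, S)),
           "dp": np.empty((T, S))}
    for t in range(T):
        for s in range(S):
            lm, dmv, dpv = fit_subject_mle(counts[t, s], d1[t, s], c1[t, s],
                                           anchor=spec.anchor)
            mle["logM"][t, s], mle["dm"][t, s], mle["dp"][t, s] = lm, dmv, dpv

    seeds = np.random.SeedSequence(seed).spawn(config.chains)
    chains = [_run_chain(counts, d1, c1, spec, config, mle, s)
              for s in seeds]

    raw = {name: np.stack([ch["group"][name] for ch in chains])  # (C, D, T)
           for name in chains[0]["group"]}
    xi = np.stack([ch["xi"] for ch in chains])  # (C, D)

    draws: dict = {"xi_M": xi}
    for t, cond in enumerate(data.conditions):
        draws[f"mu_logM_{cond}"] = raw["mu_logM"][:, :, t]
        draws[f"sigma_logM_{cond}"] = xi * raw["sig_t_M"][:, :, t]
        draws[f"mratio_{cond}"] = np.exp(raw["mu_logM"][:, :, t])
        if spec.symmetric_c2:
            loc_p, scale_p = raw["mu_c2"][:, :, t], raw["sig_c2"][:, :, t]
            loc_m, scale_m = -loc_p, scale_p
        else:
            loc_m, scale_m = raw["mu_m"][:, :, t], raw["sig_m"][:, :, t]
            loc_p, scale_p = raw["mu_p"][:, :, t], raw["sig_p"][:, :, t]
        # reported group dc2 parameters: moments of the truncated
        # subject-level distributions (identified, unlike the raw
        # location along its ridge with the scale)
        mean_p, sd_p = _truncnorm_moments(loc_p, scale_p)
        mean_m, sd_m = _truncnorm_moments(-loc_m, scale_m)
        draws[f"mu_dc2_plus_{cond}"] = mean_p
        draws[f"sigma_dc2_plus_{cond}"] = sd_p
        draws[f"mu_dc2_minus_{cond}"] = -mean_m
        draws[f"sigma_dc2_minus_{cond}"] = sd_m
        draws[f"loc_dc2_plus_{cond}"] = loc_p
        draws[f"scale_dc2_plus_{cond}"] = scale_p
        draws[f"loc_dc2_minus_{cond}"] = loc_m
        draws[f"scale_dc2_minus_{cond}"] = scale_m

    subject_draws: dict = {}
    if config.store_subject_draws:
        for name in chains[0]["subject"]:
            stacked = np.stack([ch["subject"][name] for ch in chains])
            for t, cond in enumerate(data.conditions):
                subject_draws[f"{name}_{cond}"] = stacked[:, :, t, :]

    post = PosteriorSummary(conditions=tuple(data.conditions),
                            subject_ids=list(data.subject_ids),
                            draws=draws, subject_draws=subject_draws,
                            spec=spec, config=config, seed=seed)
    if config.chains >= 2:
        diag = convergence_check(post)
        if not diag.passed:
            warnings.warn("sampler convergence check failed: "
                          + diag.message, stacklevel=2)
    return post


def fit_standard_mratio(data: CohortData, spec: ModelSpec | None = None,
                        config: SamplerConfig | None = None,
                        seed: int | None = None) -> PosteriorSummary:
    """Fit the original symmetric-criterion model (per-condition M-ratio).

    Identical preprocessing and likelihood; the group prior over the
    confidence-criterion distances is shared between |dc2-| and dc2+.
    """
    spec = replace(spec or ModelSpec(), symmetric_c2=True)
    return fit_insight_model(data, spec=spec, config=config, seed=seed)


def hdi(samples, mass: float = 0.95) -> tuple:
    """Shortest interval containing ``mass`` of the sample.

    Requires at least 100 draws (narrower samples make the interval
    estimate unstable).
    """
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie strictly between 0 and 1")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 draws for an HDI, got {n}")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def asymmetry_posterior(posterior: PosteriorSummary, condition: str,
                        basis: str = "location") -> np.ndarray:
    """Per-draw asymmetry A_t = mu_dc2+_t - |mu_dc2-_t| (flattened).

    ``basis="location"`` (default) evaluates A on the group *location*
    hyperparameters of the truncated criterion-distance priors — the
    statistic of the original formulation, whose posterior width reflects
    the location/scale uncertainty of the hierarchy.  ``basis="mean"``
    evaluates A on the truncated-distribution means (the package's
    reported group mean distances), which are more sharply identified.
    A is invariant to a shared anchor shift of both criteria under either
    basis.
    """
    if condition not in posterior.conditions:
        raise KeyError(f"condition {condition!r} not in fit "
                       f"{posterior.conditions}")
    prefix = {"location": "loc", "mean": "mu"}.get(basis)
    if prefix is None:
        raise ValueError(f"unknown basis {basis!r}; "
                         "expected 'location' or 'mean'")
    plus = posterior.flat(f"{prefix}_dc2_plus_{condition}")
    minus = posterior.flat(f"{prefix}_dc2_minus_{condition}")
    return plus - np.abs(minus)


def condition_difference(posterior: PosteriorSummary, param: str,
                         cond_a: str, cond_b: str,
                         mass: float = 0.95) -> tuple:
    """Per-draw difference ``param[cond_a] - param[cond_b]`` plus its HDI."""
    for cond in (cond_a, cond_b):
        if f"{param}_{cond}" not in posterior.draws:
            raise KeyError(f"parameter {param}_{cond} absent from fit")
    diff = (posterior.flat(f"{param}_{cond_a}")
            - posterior.flat(f"{param}_{cond_b}"))
    return diff, hdi(diff, mass) if np.ptp(diff) > 0 else (0.0, 0.0)


#: group parameters whose R-hat gates convergence (xi_M is excluded: it is
#: only identified jointly with the expanded scale it multiplies)
_DIAG_PARAMS = ("mu_logM", "sigma_logM", "mu_dc2_minus", "sigma_dc2_minus",
                "mu_dc2_plus", "sigma_dc2_plus")


def convergence_check(posterior: PosteriorSummary,
                      rhat_threshold: float = 1.05) -> DiagnosticsReport:
    """R-hat and bulk ESS for every reported group parameter.

    Passes iff all R-hat < ``rhat_threshold``.  Single-chain fits yield a
    limited report (no R-hat) and never pass.
    """
    import arviz as az

    names = [f"{p}_{c}" for p in _DIAG_PARAMS for c in posterior.conditions
             if f"{p}_{c}" in posterior.draws]
    rows = []
    n_chains = np.asarray(posterior.draws[names[0]]).shape[0]
    for name in names:
        arr = np.asarray(posterior.draws[name])
        if n_chains >= 2:
            rhat = float(az.rhat(arr))
            ess = float(az.ess(arr))
        else:
            rhat, ess = np.nan, float(az.ess(arr))
        rows.append({"parameter": name, "rhat": rhat, "ess_bulk": ess})
    table = pd.DataFrame(rows).set_index("parameter")
    if n_chains < 2:
        return DiagnosticsReport(
            table=table, passed=False,
            message="single chain: R-hat unavailable, diagnostics limited",
            rhat_threshold=rhat_threshold)
    worst = table["rhat"].max()
    passed = bool(worst < rhat_threshold)
    msg = (f"max R-hat {worst:.4f} over {len(names)} parameters "
           f"({'<' if passed else '>='} {rhat_threshold})")
    return DiagnosticsReport(table=table, passed=passed, message=msg,
                             rhat_threshold=rhat_threshold)
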