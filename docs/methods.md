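# Methods

## The measurement problem

A detection criterion shift (here: induced by congruent mental imagery)
changes how often an observer reports "present".  Whether the observer
*knows* this is not observable from Type-1 behaviour; it is observable
from where their confidence criteria sit relative to the decision
criterion.  Writing c1 for the decision criterion and c2−/c2+ for the
confidence criteria of "absent"/"present" responses, define the signed
distances Δc2− = c2− − c1 (< 0) and Δc2+ = c2+ − c1 (> 0).  If confidence
merely tracks the decision, the distances stay symmetric under a c1
shift; if the observer has insight, the confidence criteria stay anchored
near their unbiased positions and the distances become asymmetric.  The
group-level asymmetry

    A = Δc2+ − |Δc2−|

is therefore ≈ 0 without insight and > 0 with insight into a liberal
(downward) c1 shift.  A is invariant to a shared shift of both criteria,
which makes it robust to the exact c1-anchoring convention.

## First-order estimation

Equal-variance Gaussian SDT: d′ = z(H) − z(FA), c = −½(z(H) + z(FA)).
Hit rates of 1 or false-alarm rates of 0 are corrected by adding (or
subtracting) a count of 0.5 in the offending cell only, so H = 1 becomes
(n − 0.5)/n and FA = 0 becomes 0.5/n.  Continuous confidence ratings are
binarized per subject × condition by z-scoring (sample SD; configurable)
and labelling ratings strictly above 0 high — ties at z = 0 are low.
Zero-variance rating vectors are flagged rather than rejected; the
exclusion filter is the designated remover of such subjects.

## Type-2 probability model

Confidence is evaluated against a meta-level equal-variance SDT model:
evidence x ~ N(∓meta-d′/2, 1) for absent/present stimuli, with
meta-d′ = M × d′.  The Type-1 split falls at the meta-level criterion
c1′; a "present" response is high confidence iff x > c2+, an "absent"
response iff x < c2−.  Two anchoring conventions are implemented:
`"meta"` (default, the meta-d′ convention) places c1′ = c1 × M and
applies the distances Δc2 around it; `"empirical_c1"` uses the raw c1.
The model likelihood consumes only the response-conditional bin
probabilities P(conf | stim, resp); cell probabilities are clipped at
1e−12 and response probabilities below that guard yield a flagged
0.5/0.5 conditional.

## Synthetic cohorts

The built-in scenarios encode the two hypotheses about a liberal
imagery-induced criterion shift (no-imagery c1 = 0.2 vs imagery c1 = 0):

| scenario | condition | c1 | c2− | c2+ |
|---|---|---|---|---|
| both | no_imagery | 0.2 | −0.6 | 1.0 |
| no_insight | imagery | 0.0 | −0.8 | 0.8 |
| full_insight | imagery | 0.0 | −0.6 | 1.0 |

with group d′ = 2.5, M-ratio = 0.8, 100 subjects × 96 trials per
condition, between-subject σ = 0.2 for Type-1 and 0.5 for Type-2
parameters, and 50% stimulus prevalence (exact split).  Under no insight
the imagery distances stay symmetric (±0.8); under full insight the
criteria keep their no-imagery positions, making A = 0.4 at the group
values.

Subject draws: d′_s ~ N(2.5, 0.2²) and meta-d′_s ~ N(0.8 d′_s, 0.5²) are
drawn once per subject (shared across conditions; M_s = meta-d′_s/d′_s
then centres on 0.8 with the spread entering at the meta level).  The
criterion deviations (ε for c1, δ± for c2±) are likewise drawn once per
subject and applied around each condition's group values, so that each
condition's marginal is Normal(group value, σ) while a subject's
idiosyncratic criterion placement persists across conditions — the
within-subject structure the scenarios describe (criteria moving in
tandem with, or staying anchored against, the subject's own criterion).
This correlation is what makes the confidence-effect sign deterministic
across replicates; with independent per-condition draws the interaction
contrast acquires criterion noise that flips its sign in ~10% of
no-insight cohorts.  Draws violating c2− < c1 < c2+ in any condition (or
non-positive sensitivities) are rejected and redrawn, capped at 1000
attempts; at these σ's the rejection rate is a few percent and shifts the
realized mean distances outward by ≲ 0.08.

Count tables compose first-order response probabilities from (d′_s, c1_s)
with the meta-level confidence conditionals — the joint
P(resp, conf | stim) = P_1(resp | stim) P_2(conf | stim, resp).  The
default `expected` mode emits continuous expected counts (randomness then
enters only through subject parameter draws, as in the original
probability-based simulations); `multinomial` mode draws integer counts.
A trial-level synthesizer lays counts over 4 blocks × 24 trials per
condition and constructs continuous 0–100 ratings whose z-split recovers
the generating bins exactly (low/high ratings straddle the sample mean by
construction; an all-high table has no such representation and degrades
to constant ratings — with scenario parameters this never occurs).

What the generator does *not* emulate: trial-level sequential effects,
staircased visibility, d′ decrements under incongruent imagery, lapses,
or continuous confidence distributions beyond the binary bin structure.
Passing tests therefore validate the inferential machinery under the
stated generative assumptions, not the behaviour of any empirical
dataset.

## The hierarchical model

Per condition t and subject s (conditions fitted jointly):

    log M_st ~ Normal(mu_logM_t, (xi_M sigma~_M_t)²)
    Δc2−_st ~ Normal(loc−_t, scale−_t²) truncated to (−∞, 0)
    Δc2+_st ~ Normal(loc+_t, scale+_t²) truncated to (0, ∞)

Type-1 d′ and c1 enter as fixed per-subject point estimates; the
likelihood is a per-(stimulus, response) multinomial over the two
confidence bins.  Truncation enforces the criterion ordering by
construction.  Hyperpriors follow the toolbox defaults of the JAGS
lineage this model extends: Normal(0, 0.5²) on mu_logM, vague
Normal(0, 10²) on the Δc2 locations, a scale-invariant (log-uniform)
prior on the Δc2 scales (bounded to [3e−3, 3] by the sampler grid;
`half_normal` is available), half-Normal(1) on the log-M scale, and the
redundant multiplicative xi_M ~ Beta(1, 1) (Matzke-style parameter
expansion; the reported sigma_logM is xi_M·sigma~_M).  The *standard*
variant shares one group prior over |Δc2−| and Δc2+ per condition — the
original symmetric formulation used to report per-condition M-ratios.

**Identifiability and reporting.**  The truncated-normal (location,
scale) pair is only weakly identified when the truncation boundary cuts
appreciable mass: a ridge of (location, scale) combinations preserves
the truncated mean.  Two summaries are therefore exposed per side:

- `mu_dc2±` / `sigma_dc2±` — per-draw **moments of the truncated
  subject-level distribution** (the group mean and SD of the actual
  criterion distances): sharply identified, used for recovery checks and
  as the reported group means;
- `loc_dc2±` / `scale_dc2±` — the raw location/scale hyperparameters:
  ridge-widened, matching the original formulation's statistic.

`asymmetry_posterior` defaults to the location basis (`basis="location"`),
whose wide posterior reproduces the published operating characteristics —
HDIs straddling 0 under no insight, entirely positive under full
insight — and offers a `basis="mean"` variant on the truncated means.
An informative location prior (e.g. Normal(0,1)) would pull the locations
along the ridge toward zero and bias the asymmetry; hence the vague
default.

## Sampler

A Metropolis-within-Gibbs scheme in pure numpy/scipy:

- subject blocks (log M, Δc2−, Δc2+) proposed jointly per subject,
  vectorized across all subjects and conditions (conditionally
  independent given the group level), with warmup-adapted step sizes
  targeting 30% acceptance;
- group scalars drawn by **gridded independence Metropolis** from their
  full conditionals, which depend on subject values only through
  sufficient statistics (piecewise-constant proposal on a 300–450-point
  grid, exact MH correction) — mu_logM is a conjugate Gibbs draw;
- sigma~_M sampled **non-centered** (conditioning on the standardized
  subject deviations, likelihood evaluated on a 31-point grid) to
  traverse the hierarchical funnel;
- two joint expansion moves per iteration: a location shift of the whole
  log-M hierarchy, and a scale move multiplying meta-d′ together with
  all criterion distances and their group hyperparameters — the
  posterior's near-flat direction.

Defaults: 4 chains, 1000 warmup + 1000 kept draws (the analysis drivers
and acceptance script use 2 chains × 600 + 600, which keeps a full fit
near 10 s on one CPU at n = 100 while holding all group-parameter R-hat
below ≈1.05).  Chains are seeded from a spawned `SeedSequence`; fits are
bit-reproducible for a fixed seed.  Initialization jitters around
box-constrained per-subject maximum-likelihood estimates.  Diagnostics
(split R-hat, bulk ESS via arviz) cover every reported group parameter;
`convergence_check` passes iff all R-hat < 1.05.  xi_M is excluded from
the gate because it is identified only jointly with the scale it
multiplies.  The in-package `hdi` computes the shortest interval
containing the requested mass and requires ≥ 100 draws.

## Pipeline statistics

- **Exclusions**, in order: failed imagery-check blocks are dropped;
  then subjects are removed for (a) mean detection accuracy across
  conditions below 55%, (b) fewer than 2 passed blocks in any condition,
  (c) self-reported non-compliance (optional flag column), (d) more than
  90% identical confidence ratings within either response class.  All
  thresholds sit in `ExclusionConfig`.
- **Confidence effect**: per-subject interaction
  (v[imagery, present] − v[imagery, absent]) − (v[no-imagery, present] −
  v[no-imagery, absent]) on any per-response measure (high-confidence
  proportion, mean rating, mean RT), tested against 0 with a one-sample
  t-test; Cohen's d = mean/SD of the per-subject contrasts, t-based 95%
  CI.  A degenerate all-equal contrast reports t = ±inf (p = 0) rather
  than masking a nonzero constant effect.
- **First-order contrasts**: paired t-tests on d′ and c per condition
  pair, same reporting.
- **Power**: n = ceil(((z_{1−α/2} + z_power)/d)²), the normal
  approximation for a paired design; d = 0.32, α = 0.05, power = 0.90
  gives 103.
- **Simulation study**: per replicate a fresh cohort, the confidence
  effect and (optionally) the hierarchical asymmetry HDI; aggregates
  report sign and HDI-coverage proportions.  Default 20 replicates.
- No multiple-testing correction is applied anywhere (uncorrected p
  values are reported); the repeated-measures ANOVA is deliberately not
  reimplemented — the interaction contrast is the supported statistic,
  and it is what the simulation study validates.

## Problem sizes and known limitations

The test suite and acceptance script run everything at the scenario's
full cohort size (100 × 96) but with reduced MCMC draws (2 chains ×
300–600) and reduced replicate counts (5–20), chosen so the full suite
completes in minutes on one CPU; recovery-coverage checks use 40-subject
cohorts.  Known limitations: with 2 confidence bins, subject-level log M
is weakly informed and shrinks strongly toward the group mean; the
group M-ratio carries a lognormal-vs-normal gap of ≈0.02–0.03 relative
to the arithmetic generating value; the Δc2 location hyperparameters are
weakly identified (see above); and about 3–8% of no-insight cohorts are,
by subject-sampling noise alone, asymmetric enough that an honest
posterior excludes 0 — the asymmetry's sign test is reliable, its
calibration under H0 is conservative only in expectation.
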