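# metainsight

Do confidence ratings carry metacognitive insight into biases of a
perceptual decision criterion?  When imagining a stimulus while trying to
detect it, observers adopt a more liberal detection criterion — imagined
signals get mistaken for real ones.  An observer with *insight* into that
bias should become less confident in "present" responses and more
confident in "absent" responses; an observer without insight should show
the opposite, with confidence simply following the shifted criterion.

`metainsight` implements the modelling machinery to measure this, for
researchers in psychophysics and computational cognitive science:

- **First-order SDT** — d′ = z(H) − z(FA) and c = −½(z(H) + z(FA)) with the
  0.5-count correction for extreme cells, plus the within-subject z-score
  binarization of continuous confidence ratings into low/high.
- **Type-2 probability machinery** — closed-form meta-level cell
  probabilities P(resp, conf | stim) from (meta-d′, c1′, c2−, c2+), the
  shared core of the simulator and the model likelihood.
- **Synthetic cohorts** — the built-in *no-insight* (H0: confidence
  criteria move in tandem with c1) and *full-insight* (H1: criteria stay
  anchored) scenarios: 100 subjects × 96 trials/condition, d′ = 2.5,
  M-ratio = 0.8, Gaussian between-subject spread (σ = 0.2 Type-1,
  0.5 Type-2).
- **A hierarchical Bayesian meta-d′ model with asymmetric
  confidence-criterion priors** — subject-level multinomial likelihoods
  over confidence bins with independent group priors on the negative and
  positive criterion distances Δc2± = c2± − c1, fitted jointly across
  conditions by a built-in MCMC sampler.  The headline statistic is the
  posterior asymmetry **A = Δc2+ − |Δc2−|**: ≈0 without insight, >0 with
  insight.
- **Study pipeline** — exclusion filters, paired first-order contrasts,
  the condition × response interaction contrast on confidence ("the
  confidence effect"), the replicated H0/H1 simulation study, and the
  paired-design power calculation.

## Worked example

```python
import metainsight as mi
from metainsight.model import CohortData, SamplerConfig

cohort = mi.simulate_cohort(mi.make_scenario("full_insight"), seed=1)
post = mi.fit_insight_model(CohortData.from_cohort(cohort),
                            config=SamplerConfig(chains=2, draws=600,
                                                 warmup=600), seed=1)
a = mi.asymmetry_posterior(post, "imagery")
lo, hi = mi.hdi(a)
print(f"A = {a.mean():.3f}, 95% HDI = ({lo:.3f}, {hi:.3f})")
print(f"M-ratio = {post.mean_of('mratio_imagery'):.3f}")
```

prints (to MCMC noise)

```
A = 0.629, 95% HDI = (0.380, 0.986)
M-ratio = 0.751
```

The cohort was generated under *full insight* (imagery criteria anchored
at the no-imagery positions c2− = −0.6, c2+ = 1.0 despite the c1 shift of
0.2), so the asymmetry is credibly positive — the distance to the positive
confidence criterion exceeds the distance to the negative one.  The same
fit on a *no-insight* cohort (symmetric ±0.8 distances) yields an HDI
straddling 0.  The recovered group metacognitive efficiency sits near the
generating M-ratio of 0.8.

The numbered drivers under `analysis/` run the full study — scenario
definitions, the 20-replicate confidence-effect sign study, the
hierarchical asymmetry fits and the power analysis — and write their
tables under `results/`:

```sh
python analysis/01_define_scenarios.py
python analysis/02_confidence_effect_study.py
python analysis/03_fit_asymmetry.py
python analysis/04_power_analysis.py
```

A `metainsight` CLI wraps the same functionality
(`metainsight simulate|fit|analyze|simstudy|power --help`).

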