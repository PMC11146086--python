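"""Hierarchical Bayesian asymmetry fits under both hypotheses.

Simulates one full-size cohort per scenario, fits the asymmetric
confidence-criterion model, and summarizes the imagery-condition
asymmetry A = mu_dc2+ - |mu_dc2-|: its 95% HDI straddles 0 under no
insight and lies entirely above 0 under full insight.  Also fits the
standard symmetric model to report group metacognitive efficiency.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

import metainsight as mi
from metainsight import io
from metainsight.model import CohortData, SamplerConfig

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--draws", type=int, default=600)
    parser.add_argument("--chains", type=int, default=2)
    args = parser.parse_args()
    warnings.filterwarnings("ignore")
    OUT.mkdir(exist_ok=True)

    config = SamplerConfig(chains=args.chains, draws=args.draws,
                           warmup=args.draws)
    seeds = np.random.SeedSequence(args.seed).spawn(4)
    rows = []
    for k, name in enumerate(("no_insight", "full_insight")):
        cohort = mi.simulate_cohort(
            mi.make_scenario(name),
            seed=int(seeds[k].generate_state(1)[0] % 2 ** 31),
            mode="expected")
        data = CohortData.from_cohort(cohort)
        post = mi.fit_insight_model(
            data, config=config,
            seed=int(seeds[k + 2].generate_state(1)[0] % 2 ** 31))
        io.write_posterior_summary(post, OUT / f"posterior_summary_{name}.csv")
        diag = mi.convergence_check(post)
        a = mi.asymmetry_posterior(post, "imagery")
        lo, hi = mi.hdi(a)
        rows.append({
            "scenario": name, "a_mean": round(float(a.mean()), 4),
            "a_hdi_low": round(lo, 4), "a_hdi_high": round(hi, 4),
            "hdi_contains_zero": bool(lo <= 0 <= hi),
            "max_rhat": round(float(diag.table["rhat"].max()), 4),
        })
        if name == "no_insight":
            post_std = mi.fit_standard_mratio(data, config=config,
                                              seed=args.seed)
            mr = pd.DataFrame([
                {"condition": c,
                 "mratio_mean": round(post_std.mean_of(f"mratio_{c}"), 4),
                 "hdi_low": round(post_std.hdi_of(f"mratio_{c}")[0], 4),
                 "hdi_high": round(post_std.hdi_of(f"mratio_{c}")[1], 4)}
                for c in post_std.conditions])
            mr.to_csv(OUT / "mratio_standard_model.csv", index=False)
            print("Standard-model metacognitive efficiency (generating "
                  "M-ratio 0.8):")
            print(mr.to_string(index=False), "\n")

    table = pd.DataFrame(rows)
    table.to_csv(OUT / "asymmetry_hdi.csv", index=False)
    print("Imagery-condition asymmetry posteriors:")
    print(table.to_string(index=False))
    print("\nReading: the no-insight cohort's asymmetry HDI straddles 0 "
          "(confidence criteria moved with the decision criterion), the "
          "full-insight cohort's lies above 0 (criteria stayed anchored).")


if __name__ == "__main__":
    main()
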