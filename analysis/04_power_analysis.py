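"""Preregistered-style power analysis for the paired criterion contrast.

Normal-approximation sample sizes for a within-subject design across a
range of effect sizes, anchored at the study's observed criterion-shift
effect size of d = 0.32.
"""

from pathlib import Path

import pandas as pd

import metainsight as mi

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = [{"effect_size": d, "alpha": 0.05, "power": 0.90,
             "required_n": mi.power_required_n(d, 0.05, 0.90)}
            for d in (0.2, 0.25, 0.32, 0.4, 0.5)]
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "power_analysis.csv", index=False)
    print(table.to_string(index=False))
    print("\nReading: detecting the observed criterion-shift effect "
          "(d = 0.32) with 90% power at two-sided alpha = 0.05 requires "
          "103 participants.")


if __name__ == "__main__":
    main()
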