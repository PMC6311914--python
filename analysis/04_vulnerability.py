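"""Within-bin vulnerability of T2D cells in the two stressed cohorts.

Cells are binned L/M/H along each stress axis (oxidative: JNK with
thresholds 4/8; ER: ATF6 and caspase: CASP6 with thresholds 2/4, all on the
log2 scale), then healthy and T2D median INS are compared within each bin.
Writes results/analysis/vulnerability.tsv.
"""

from pathlib import Path

import pandas as pd

from betacell.preprocess import log2_transform
from betacell.stress import (DEFAULT_THRESHOLDS, bin_stress,
                             compute_stress_scores, vulnerability_compare)
from betacell.synthetic_data import scenario_config, simulate_cohort

OUT = Path("results/analysis")
SEED = 0


def main() -> None:
    parts = []
    for name in ("dataset2_like", "dataset3_like"):
        cohort = simulate_cohort(scenario_config(name, seed=SEED))
        expr_log2 = log2_transform(cohort.expression)
        cond = cohort.annotation.condition_of(cohort.expression.cell_ids)
        scores = compute_stress_scores(cohort.expression, expr_log2)
        for axis, thr in DEFAULT_THRESHOLDS.items():
            bins = bin_stress(scores.axes[axis], axis, thr)
            table = vulnerability_compare(expr_log2.gene("INS"), bins, cond)
            table.insert(0, "cohort", name)
            parts.append(table)
        oxid = parts[-3].set_index("bin")
        print(f"{name}: oxidative-bin INS percent difference "
              f"L={oxid.loc['L', 'percent_difference']:.1f}% "
              f"M={oxid.loc['M', 'percent_difference']:.1f}% "
              f"H={oxid.loc['H', 'percent_difference']:.1f}%")
    OUT.mkdir(parents=True, exist_ok=True)
    pd.concat(parts, ignore_index=True).to_csv(
        OUT / "vulnerability.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"\nwrote {OUT / 'vulnerability.tsv'}")


if __name__ == "__main__":
    main()
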