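"""Simulate the three scenario cohorts and write them to disk.

The three presets emulate the regimes of the underlying study design:
a low-stress null cohort, a cohort where only T2D cells are stressed, and a
cohort where both conditions carry high stress. Outputs one directory per
cohort (expression.tsv, cells.tsv, truth.tsv, scenario_config.json) under
results/analysis/cohorts/.
"""

from pathlib import Path

from betacell.synthetic_data import PRESETS, scenario_config, simulate_cohort, write_cohort

OUT = Path("results/analysis/cohorts")
SEED = 0


def main() -> None:
    print("scenario          donors(H/T2D)  cells(H/T2D)")
    for name in PRESETS:
        cohort = simulate_cohort(scenario_config(name, seed=SEED))
        write_cohort(cohort, OUT / name)
        counts = cohort.annotation.counts()
        donors = cohort.annotation.table.groupby("condition")["donor_id"].nunique()
        print(f"{name:<18}{donors['healthy']}/{donors['T2D']:<13}"
              f"{counts['healthy']}/{counts['T2D']}")
    print(f"\nwrote cohorts to {OUT}")


if __name__ == "__main__":
    main()
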