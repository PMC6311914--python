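"""Multi-seed simulation studies over the scenario generator.

Each function runs one of the headline analyses across many independently
seeded cohorts and reports recovery/qualitative-pattern rates:

* does MI attribution recover oxidative stress as the dominant INS factor
  when the generator couples INS to it most strongly?
* do the five LOOCV classifiers sit at the majority baseline in the null
  regime and discriminate well under a strong stress gap?
* does the healthy-vs-T2D median INS percent difference grow monotonically
  across oxidative stress bins under positive coupling, and centre on zero
  without coupling?
* do the apoptosis-pathway genes that drive the caspase latent come out on
  top of the PCA-loading and MI screens?

All randomness flows from ``base_seed`` (cohort i uses base_seed + i).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .apoptosis import loading_screen, mi_screen, pca_project
from .classify import (CLASSIFIER_KINDS, build_feature_table, evaluate_all,
                       majority_baseline)
from .data_io import load_apoptosis_panel, load_stress_panel
from .infotheory import mi_attribution
from .preprocess import FilterSpec, filter_genes, log2_transform
from .stress import (DEFAULT_THRESHOLDS, bin_stress, compute_stress_scores,
                     vulnerability_compare)
from .synthetic_data import scenario_config, simulate_cohort

CASPASES = frozenset({"CASP3", "CASP6", "CASP7"})


def _prepared_cohort(scenario: str, seed: int, **overrides):
    cohort = simulate_cohort(scenario_config(scenario, seed=seed, **overrides))
    expr_log2 = log2_transform(cohort.expression)
    cond = cohort.annotation.condition_of(cohort.expression.cell_ids)
    scores = compute_stress_scores(cohort.expression, expr_log2)
    return cohort, expr_log2, cond, scores


def mi_attribution_study(n_seeds: int = 50, scenario: str = "dataset2_like",
                         base_seed: int = 0, cells: str = "t2d") -> pd.DataFrame:
    """Per-seed MI of INS against the three stress axes on fresh cohorts.

    Returns one row per seed with each axis' MI (bits) and the winning axis;
    on T2D cells by default, mirroring the factor-attribution analysis.
    """
    rows = []
    for i in range(n_seeds):
        cohort, expr_log2, cond, scores = _prepared_cohort(scenario,
                                                           base_seed + i)
        if cells == "t2d":
            ids = [c for c in cohort.expression.cell_ids if cond[c] == "T2D"]
        else:
            ids = cohort.expression.cell_ids
        table = mi_attribution(
            expr_log2.gene("INS").loc[ids],
            {axis: scores.axes.loc[ids, axis] for axis in scores.axes.columns})
        row = {"seed": base_seed + i, "top_factor": table.iloc[0]["factor"]}
        for _, r in table.iterrows():
            row[f"mi_{r['factor']}"] = r["mutual_information"]
        rows.append(row)
    return pd.DataFrame(rows)


def classification_study(seed: int = 0,
                         scenarios: tuple[str, ...] = ("dataset1_like",
                                                       "dataset2_like"),
                         kinds: tuple[str, ...] = CLASSIFIER_KINDS,
                         ) -> pd.DataFrame:
    """LOOCV metrics of the five classifiers per scenario, with the
    majority-class baseline attached.

    The expressed-gene filter runs once per cohort with the minority-class
    fraction rule before cross-validation, as in the underlying protocol.
    """
    panel = load_stress_panel()
    parts = []
    for scenario in scenarios:
        cohort, expr_log2, _, _ = _prepared_cohort(scenario, seed)
        fres = filter_genes(cohort.expression, panel,
                            FilterSpec(fraction_rule="minority_class"),
                            ann=cohort.annotation)
        table = build_feature_table(expr_log2, cohort.annotation,
                                    fres.kept.symbols, name=f"{scenario}_own")
        metrics = evaluate_all(table, kinds=kinds, seed=seed)
        metrics.insert(0, "scenario", scenario)
        metrics["n_features"] = len(fres.kept)
        metrics["majority_baseline"] = majority_baseline(table.y)
        parts.append(metrics)
    return pd.concat(parts, ignore_index=True)


def vulnerability_study(n_seeds: int = 25, scenario: str = "dataset3_like",
                        base_seed: int = 0, axis: str = "oxidative",
                        **overrides) -> pd.DataFrame:
    """Per-seed within-bin INS percent differences along one stress axis.

    Returns one row per seed with the L/M/H percent differences, whether any
    bin was skipped for want of cells, and whether the differences increase
    strictly from L to M to H.
    """
    rows = []
    for i in range(n_seeds):
        cohort, expr_log2, cond, scores = _prepared_cohort(
            scenario, base_seed + i, **overrides)
        bins = bin_stress(scores.axes[axis], axis, DEFAULT_THRESHOLDS[axis])
        table = vulnerability_compare(expr_log2.gene("INS"), bins, cond)
        pct = table.set_index("bin")["percent_difference"]
        complete = not table["skipped"].any()
        rows.append({
            "seed": base_seed + i,
            "pct_L": pct["L"], "pct_M": pct["M"], "pct_H": pct["H"],
            "all_bins_occupied": complete,
            "monotone": bool(complete and pct["L"] < pct["M"] < pct["H"]),
        })
    return pd.DataFrame(rows)


def apoptosis_recovery_study(n_seeds: int = 25,
                             scenario: str = "dataset2_like",
                             base_seed: int = 0) -> pd.DataFrame:
    """Per-seed driver recovery by the PCA-loading and MI screens.

    The generator couples its configured driver genes most strongly to the
    caspase latent. PCA recovery asks whether those drivers hold the top-3
    loading ranks over the full 24-gene panel (all cells); MI recovery asks
    whether they hold the top-3 MI-vs-TEDECs ranks among the non-caspase
    panel genes on T2D cells (the caspases themselves compose the TEDECs
    total and are excluded from the ranking).
    """
    panel = load_apoptosis_panel()
    rows = []
    for i in range(n_seeds):
        cohort, expr_log2, cond, scores = _prepared_cohort(scenario,
                                                           base_seed + i)
        drivers = set(cohort.config.apoptosis_drivers)
        proj = pca_project(expr_log2, panel)
        top_loadings = set(loading_screen(proj).head(len(drivers))["gene"])
        t2d = [c for c in cohort.expression.cell_ids if cond[c] == "T2D"]
        screen = mi_screen(expr_log2, panel, scores.tedecs, cells=t2d)
        ranked = (screen[~screen["gene"].isin(CASPASES)]
                  .sort_values("mutual_information", ascending=False))
        top_mi = set(ranked.head(len(drivers))["gene"])
        rows.append({
            "seed": base_seed + i,
            "pca_recovered": top_loadings == drivers,
            "mi_recovered": top_mi == drivers,
        })
    return pd.DataFrame(rows)
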