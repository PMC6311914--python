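"""Composite stress scores, stress-level binning, and the vulnerability
comparison of healthy vs T2D INS expression within matched stress bins.

Conventions
-----------
* TEDECs (total expression of the death executioner caspases) is the raw-scale
  per-cell sum of CASP3 + CASP6 + CASP7 — a "total expression level", so it is
  accumulated before any log transform.
* The three stress axes are represented by single well-expressed genes:
  oxidative stress by JNK, ER stress by ATF6, executioner-caspase activity by
  CASP6. Axis values and bin thresholds live on the log2(x+1) scale, where
  the canonical thresholds (4, 8) for oxidative stress and (2, 4) for the
  other two axes are natural magnitudes.
* Bins are lower-inclusive: L iff value < t_low; M iff t_low <= value <
  t_high; H iff value >= t_high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc_stats import t_test
from .data_io import ExpressionMatrix

CASPASE_GENES = ("CASP3", "CASP6", "CASP7")

#: representative gene per stress axis
DEFAULT_REPRESENTATIVES = {"oxidative": "JNK", "ER": "ATF6", "caspase": "CASP6"}

#: (t_low, t_high) per axis on the log2(x+1) scale
DEFAULT_THRESHOLDS = {"oxidative": (4.0, 8.0), "ER": (2.0, 4.0), "caspase": (2.0, 4.0)}

BIN_LABELS = ("L", "M", "H")


def compute_tedecs(expr: ExpressionMatrix) -> pd.Series:
    """Per-cell raw-scale sum of the executioner caspases CASP3/CASP6/CASP7.

    Missing caspase genes contribute 0 with a warning; if all three are
    absent the score is all zeros (also warned).
    """
    if expr.scale != "raw":
        raise ValueError("TEDECs is a total of raw-scale expression values")
    present = [g for g in CASPASE_GENES if g in expr.data.index]
    missing = [g for g in CASPASE_GENES if g not in expr.data.index]
    if missing:
        warnings.warn(f"TEDECs: caspase genes absent from matrix: {missing}",
                      stacklevel=2)
    if not present:
        return pd.Series(0.0, index=expr.data.columns, name="tedecs")
    return expr.data.loc[present].sum(axis=0).rename("tedecs")


def representative_axes(expr_log2: ExpressionMatrix,
                        representatives: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-cell log2-scale values of the representative gene of each axis."""
    if expr_log2.scale != "log2":
        raise ValueError("axis representatives are read on the log2 scale")
    reps = representatives or DEFAULT_REPRESENTATIVES
    cols = {}
    for axis, gene in reps.items():
        if gene not in expr_log2.data.index:
            raise KeyError(f"representative gene {gene!r} for axis {axis!r} "
                           "not in matrix")
        cols[axis] = expr_log2.gene(gene)
    return pd.DataFrame(cols)


@dataclass
class StressBins:
    """L/M/H stress-level assignment of every cell along one axis."""

    axis: str
    thresholds: tuple[float, float]
    labels: pd.Series  # index = cell ids, values in {"L","M","H"}

    @property
    def counts(self) -> dict[str, int]:
        c = self.labels.value_counts().to_dict()
        return {lab: int(c.get(lab, 0)) for lab in BIN_LABELS}


def bin_stress(values: pd.Series, axis: str,
               thresholds: tuple[float, float]) -> StressBins:
    """Partition cells into low/medium/high stress along one axis.

    Boundary convention is lower-inclusive: a value exactly at t_low is M, a
    value exactly at t_high is H.
    """
    t_low, t_high = thresholds
    if not t_low < t_high:
        raise ValueError("thresholds must satisfy t_low < t_high")
    v = values.astype(float)
    labels = pd.Series(
        np.where(v < t_low, "L", np.where(v < t_high, "M", "H")),
        index=v.index, name=f"{axis}_bin",
    )
    empty = [lab for lab, n in
             StressBins(axis, thresholds, labels).counts.items() if n == 0]
    if empty:
        warnings.warn(f"bin_stress({axis}): empty bins {empty}", stacklevel=2)
    return StressBins(axis=axis, thresholds=(float(t_low), float(t_high)),
                      labels=labels)


def vulnerability_compare(ins_log2: pd.Series, bins: StressBins,
                          condition: pd.Series,
                          min_cells: int = 2) -> pd.DataFrame:
    """Healthy-vs-T2D INS comparison within each stress bin.

    Per bin: the two group medians of log2 INS, the percent difference
    (median_healthy - median_T2D) / median_healthy * 100 (healthy is the
    reference), a Student's t-test p-value and its significance flag at 0.05.
    Bins with fewer than ``min_cells`` cells in either condition are reported
    with skipped=True and no statistics; a healthy median of exactly 0 makes
    the percent difference undefined (NaN, flagged).
    """
    rows = []
    for lab in BIN_LABELS:
        in_bin = bins.labels == lab
        h = ins_log2[in_bin & (condition == "healthy")]
        t = ins_log2[in_bin & (condition == "T2D")]
        row = {"axis": bins.axis, "bin": lab,
               "n_healthy": int(h.size), "n_t2d": int(t.size)}
        if h.size < min_cells or t.size < min_cells:
            row.update({"skipped": True, "median_healthy": np.nan,
                        "median_t2d": np.nan, "percent_difference": np.nan,
                        "t_statistic": np.nan, "p_value": np.nan,
                        "significant": False, "undefined_reference": False})
            rows.append(row)
            continue
        cmp = t_test(h, t)
        med_h, med_t = cmp.median_a, cmp.median_b
        if med_h == 0:
            pct = np.nan
            undefined = True
        else:
            pct = (med_h - med_t) / med_h * 100.0
            undefined = False
        row.update({"skipped": False, "median_healthy": med_h,
                    "median_t2d": med_t, "percent_difference": pct,
                    "t_statistic": cmp.t_statistic, "p_value": cmp.p_value,
                    "significant": cmp.significant,
                    "undefined_reference": undefined})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StressScores:
    """Per-cell composite scores: TEDECs and the three representative axes."""

    tedecs: pd.Series
    axes: pd.DataFrame  # columns oxidative / ER / caspase, log2 scale
    representatives: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REPRESENTATIVES))


def compute_stress_scores(expr_raw: ExpressionMatrix,
                          expr_log2: ExpressionMatrix,
                          representatives: dict[str, str] | None = None
                          ) -> StressScores:
    reps = representatives or DEFAULT_REPRESENTATIVES
    return StressScores(tedecs=compute_tedecs(expr_raw),
                        axes=representative_axes(expr_log2, reps),
                        representatives=dict(reps))
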