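"""Personalized per-donor summaries of INS expression and TEDECs."""

from __future__ import annotations

import pandas as pd

from .data_io import CellAnnotation


def summarize_donors(ins_log2: pd.Series, tedecs: pd.Series,
                     ann: CellAnnotation) -> tuple[pd.DataFrame, dict]:
    """One row per donor (healthy donors first, then T2D, in annotation
    order) with cell count and median/mean INS (log2) and TEDECs (raw).

    The returned flags record cross-group ordering facts:

    * ``all_t2d_ins_below_all_healthy`` — every T2D donor's median INS is
      below every healthy donor's median INS;
    * ``all_t2d_tedecs_above_all_healthy`` — every T2D donor's median TEDECs
      exceeds every healthy donor's median TEDECs.

    Donors with a single cell are flagged ``low_n``.
    """
    tab = ann.table
    rows = []
    for cond in ("healthy", "T2D"):
        for donor in tab.loc[tab["condition"] == cond, "donor_id"].unique():
            cells = tab.loc[tab["donor_id"] == donor, "cell_id"]
            ins = ins_log2.loc[cells]
            ted = tedecs.loc[cells]
            rows.append({
                "donor_id": donor, "condition": cond,
                "cohort": tab.loc[tab["donor_id"] == donor, "cohort"].iloc[0],
                "n_cells": int(len(cells)),
                "median_ins": float(ins.median()),
                "mean_ins": float(ins.mean()),
                "median_tedecs": float(ted.median()),
                "mean_tedecs": float(ted.mean()),
                "low_n": bool(len(cells) < 2),
            })
    table = pd.DataFrame(rows)
    h = table[table["condition"] == "healthy"]
    t = table[table["condition"] == "T2D"]
    flags = {
        "all_t2d_ins_below_all_healthy": bool(
            len(h) and len(t) and t["median_ins"].max() < h["median_ins"].min()),
        "all_t2d_tedecs_above_all_healthy": bool(
            len(h) and len(t)
            and t["median_tedecs"].min() > h["median_tedecs"].max()),
    }
    return table, flags
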