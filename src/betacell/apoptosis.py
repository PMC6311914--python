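"""Apoptosis-pathway analysis: MI screen against TEDECs and PCA projection.

The screen computes, per apoptosis-pathway gene, the discrete mutual
information between that gene and the TEDECs apoptosis proxy (both
floor-discretized on the log2(x+1) scale, matching the infotheory
conventions), and flags genes above the 0.6-bit line as remarkable.
The PCA projects cells, characterized by the 24 pathway genes, onto the
first two principal components of the gene-centered log2 matrix (no
unit-variance scaling); component signs are fixed so the largest-magnitude
loading of each component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data_io import ExpressionMatrix, GenePanel
from .infotheory import discretize, mutual_information

MI_REMARKABLE_THRESHOLD = 0.6


def mi_screen(expr_log2: ExpressionMatrix, panel: GenePanel,
              tedecs: pd.Series, cells: list[str] | None = None,
              threshold: float = MI_REMARKABLE_THRESHOLD) -> pd.DataFrame:
    """MI of every panel gene against TEDECs over the given cells.

    ``tedecs`` is the raw-scale caspase total; it is brought onto the
    log2(x+1) scale before floor discretization so both variables share the
    discretization convention. Rows keep panel order; ``mi_rank`` ranks by
    MI descending.
    """
    if expr_log2.scale != "log2":
        raise ValueError("MI screen expects log2-scale expression")
    cell_ids = list(cells) if cells is not None else expr_log2.cell_ids
    t = discretize(np.log2(tedecs.loc[cell_ids].to_numpy() + 1.0))
    rows = []
    for sym in panel.symbols:
        if sym not in expr_log2.data.index:
            rows.append({"gene": sym, "entropy_tedecs": np.nan,
                         "entropy_gene": np.nan, "joint_entropy": np.nan,
                         "mutual_information": np.nan, "remarkable": False,
                         "missing": True})
            continue
        g = discretize(expr_log2.data.loc[sym, cell_ids].to_numpy())
        res = mutual_information(t, g)
        rows.append({"gene": sym, "entropy_tedecs": res.h_x,
                     "entropy_gene": res.h_y, "joint_entropy": res.h_xy,
                     "mutual_information": res.mi,
                     "remarkable": bool(res.mi > threshold), "missing": False})
    table = pd.DataFrame(rows)
    order = table["mutual_information"].rank(ascending=False, method="first")
    table["mi_rank"] = order.astype("Int64")
    return table


@dataclass
class PcaProjection:
    """Top-2 principal components of the pathway-gene expression."""

    loadings: pd.DataFrame  # genes x (PC1, PC2), orthonormal columns
    scores: pd.DataFrame  # cells x (PC1, PC2)
    variance_fraction: np.ndarray  # length 2, PC1 >= PC2


def pca_project(expr_log2: ExpressionMatrix, panel: GenePanel,
                cells: list[str] | None = None) -> PcaProjection:
    """Project cells onto the first two principal components of the
    gene-centered log2 matrix (covariance PCA, no scaling).

    Deterministic: each component's largest-magnitude loading is made
    positive. Requires at least 3 cells and 2 panel genes present.
    """
    if expr_log2.scale != "log2":
        raise ValueError("PCA expects log2-scale expression")
    cell_ids = list(cells) if cells is not None else expr_log2.cell_ids
    if len(cell_ids) < 3:
        raise ValueError("PCA needs at least 3 cells")
    genes = [g for g in panel.symbols if g in expr_log2.data.index]
    if len(genes) < 2:
        raise ValueError("PCA needs at least 2 panel genes present")
    X = expr_log2.data.loc[genes, cell_ids].to_numpy().T  # cells x genes
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x 2
    for k in range(2):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
            scores[:, k] = -scores[:, k]
    return PcaProjection(
        loadings=pd.DataFrame(loadings, index=genes, columns=["PC1", "PC2"]),
        scores=pd.DataFrame(scores, index=cell_ids, columns=["PC1", "PC2"]),
        variance_fraction=pca.explained_variance_ratio_.copy(),
    )


def loading_screen(proj: PcaProjection) -> pd.DataFrame:
    """Rank genes by their largest absolute loading over PC1/PC2.

    The "large" flag marks magnitudes above mean + 1 sd of all magnitudes —
    a documented heuristic for 'larger than others', not a significance
    test.
    """
    mag = proj.loadings.abs().max(axis=1)
    cut = mag.mean() + mag.std(ddof=0)
    table = pd.DataFrame({
        "gene": proj.loadings.index,
        "loading_pc1": proj.loadings["PC1"].to_numpy(),
        "loading_pc2": proj.loadings["PC2"].to_numpy(),
        "max_abs_loading": mag.to_numpy(),
    })
    table = table.sort_values("max_abs_loading", ascending=False,
                              kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["large"] = table["max_abs_loading"] > cut
    return table
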