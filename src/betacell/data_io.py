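"""Containers and readers/writers for expression matrices, cell metadata and gene panels.

The in-memory contract mirrors how the downstream analyses consume data:

* :class:`ExpressionMatrix` — genes x cells, non-negative, with an explicit
  ``scale`` marker (``"raw"`` for RPKM/TPM-like linear values, ``"log2"`` after
  the log transform) so that scale-sensitive steps can refuse wrong input.
* :class:`CellAnnotation` — per-cell donor id, condition (healthy/T2D) and
  cohort tag.
* :class:`GenePanel` — an ordered gene list with category tags and optional
  protein-style aliases (the literature writes JNK where HGNC writes MAPK8).

On disk everything is plain TSV/CSV (header row = cell ids, first column =
gene symbols); an MTX triple (matrix.mtx + genes.tsv + cells.tsv) is supported
for interoperability with the usual single-cell tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

HEALTHY = "healthy"
T2D = "T2D"
CONDITIONS = (HEALTHY, T2D)

PANEL_CATEGORIES = (
    "ER_stress",
    "oxidative_stress",
    "executioner_caspase",
    "INS_related",
    "apoptosis_pathway",
)


class DataValidationError(ValueError):
    """Raised when an input file or matrix violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values with an explicit scale marker.

    Parameters
    ----------
    data
        DataFrame indexed by gene symbol with cell ids as columns.
    scale
        ``"raw"`` for linear RPKM/TPM-like values (must be non-negative) or
        ``"log2"`` for log2(x + pseudocount) transformed values.
    """

    data: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise DataValidationError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate cell ids: {dups}")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise DataValidationError("expression matrix contains non-finite values")
        if self.scale == "raw" and (values < 0).any():
            g, c = np.argwhere(values < 0)[0]
            raise DataValidationError(
                f"negative expression value at gene {self.data.index[g]!r}, "
                f"cell {self.data.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def cell_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(cell_ids)], scale=self.scale)

    def gene(self, symbol: str) -> pd.Series:
        """Per-cell values of one gene."""
        return self.data.loc[symbol]


@dataclass
class CellAnnotation:
    """Per-cell metadata: cell_id, donor_id, condition, cohort."""

    table: pd.DataFrame

    REQUIRED = ("cell_id", "donor_id", "condition", "cohort")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataValidationError(f"annotation missing columns: {missing}")
        if self.table["cell_id"].duplicated().any():
            dups = self.table.loc[self.table["cell_id"].duplicated(), "cell_id"].tolist()
            raise DataValidationError(f"duplicate cell annotations: {dups}")
        bad = set(self.table["condition"]) - set(CONDITIONS)
        if bad:
            raise DataValidationError(
                f"unknown condition labels {sorted(bad)}; expected {CONDITIONS}"
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def cell_ids(self) -> list[str]:
        return self.table["cell_id"].tolist()

    def condition_of(self, cell_ids: Sequence[str]) -> pd.Series:
        cond = self.table.set_index("cell_id")["condition"]
        return cond.loc[list(cell_ids)]

    def donor_of(self, cell_ids: Sequence[str]) -> pd.Series:
        donor = self.table.set_index("cell_id")["donor_id"]
        return donor.loc[list(cell_ids)]

    def counts(self) -> dict[str, int]:
        return self.table["condition"].value_counts().to_dict()


@dataclass
class GenePanel:
    """Ordered gene list with category tags and optional aliases."""

    table: pd.DataFrame
    name: str = "panel"

    def __post_init__(self) -> None:
        if "symbol" not in self.table.columns or "category" not in self.table.columns:
            raise DataValidationError("panel needs 'symbol' and 'category' columns")
        if "alias" not in self.table.columns:
            self.table = self.table.assign(alias="")
        self.table["alias"] = self.table["alias"].fillna("")
        if self.table["symbol"].duplicated().any():
            dups = self.table.loc[self.table["symbol"].duplicated(), "symbol"].tolist()
            raise DataValidationError(f"duplicate panel symbols: {dups}")
        bad = set(self.table["category"]) - set(PANEL_CATEGORIES)
        if bad:
            raise DataValidationError(f"unknown panel categories: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def symbols(self) -> list[str]:
        return self.table["symbol"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def category(self, category: str) -> list[str]:
        return self.table.loc[self.table["category"] == category, "symbol"].tolist()

    def alias_map(self) -> dict[str, str]:
        """alias -> primary symbol (aliases resolve literature names like MAPK8)."""
        out = {}
        for _, row in self.table.iterrows():
            if row["alias"]:
                out[row["alias"]] = row["symbol"]
        return out

    def subset(self, symbols: Iterable[str], name: str | None = None) -> "GenePanel":
        keep = set(symbols)
        sub = self.table[self.table["symbol"].isin(keep)].reset_index(drop=True)
        return GenePanel(sub, name=name or self.name)


# ---------------------------------------------------------------------------
# expression IO
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, format: str = "tsv",
                    scale: str = "raw") -> ExpressionMatrix:
    """Read a genes x cells expression matrix.

    TSV/CSV: header row of cell ids, first column gene symbols. MTX: ``path``
    is the .mtx file; ``genes.tsv`` and ``cells.tsv`` sidecars must sit next
    to it. Zeros are kept as zeros, never treated as missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        try:
            df = df.astype(float)
        except ValueError as exc:
            raise DataValidationError(f"non-numeric expression values in {path}: {exc}")
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        genes = pd.read_csv(path.parent / "genes.tsv", sep="\t", header=None)[0].astype(str)
        cells = pd.read_csv(path.parent / "cells.tsv", sep="\t", header=None)[0].astype(str)
        df = pd.DataFrame(np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat),
                          index=genes, columns=cells)
    else:
        raise ValueError(f"unknown format {format!r}")
    return ExpressionMatrix(df, scale=scale)


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     format: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        expr.data.to_csv(path, sep=sep, float_format="%.8g", index_label="gene")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(expr.data.to_numpy()),
                         precision=8)
        pd.Series(expr.gene_ids).to_csv(path.parent / "genes.tsv", sep="\t",
                                        header=False, index=False)
        pd.Series(expr.cell_ids).to_csv(path.parent / "cells.tsv", sep="\t",
                                        header=False, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_annotation(path: str | Path) -> CellAnnotation:
    return CellAnnotation(pd.read_csv(path, sep="\t", dtype=str))


def write_annotation(ann: CellAnnotation, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ann.table.to_csv(path, sep="\t", index=False)


def read_gene_panel(path: str | Path, name: str | None = None) -> GenePanel:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    return GenePanel(table, name=name or path.stem)


def write_gene_panel(panel: GenePanel, path: str | Path) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


def load_stress_panel() -> GenePanel:
    """The bundled 45-gene stress/INS panel (ER stress, oxidative stress,
    executioner caspases, INS-related genes).

    This is a curated reconstruction (hence the ``_synthetic`` filename):
    it anchors on the pathway members named in the study of record and is
    padded with standard ER-stress / oxidative-stress / beta-cell-identity
    genes to the published panel size of 45.
    """
    ref = resources.files("betacell.panels") / "stress45_synthetic.tsv"
    with resources.as_file(ref) as p:
        return read_gene_panel(p, name="stress45")


def load_apoptosis_panel() -> GenePanel:
    """The bundled 24-gene apoptosis-pathway panel (death-receptor,
    mitochondrial, TP53 and ER-stress mediated arms). Curated reconstruction,
    see :func:`load_stress_panel`."""
    ref = resources.files("betacell.panels") / "apoptosis24_synthetic.tsv"
    with resources.as_file(ref) as p:
        return read_gene_panel(p, name="apoptosis24")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedCohort:
    """Expression restricted to annotated cells, in expression-column order."""

    expression: ExpressionMatrix
    annotation: CellAnnotation
    dropped_cells: list[str] = field(default_factory=list)


def align(expr: ExpressionMatrix, ann: CellAnnotation,
          min_per_condition: int = 2) -> AlignedCohort:
    """Join expression with annotation on cell id.

    Keeps cells present in both, in expression order; reports dropped cells.
    Fails if fewer than ``min_per_condition`` cells per condition remain.
    """
    annotated = set(ann.cell_ids)
    keep = [c for c in expr.cell_ids if c in annotated]
    dropped = [c for c in expr.cell_ids if c not in annotated]
    if not keep:
        raise DataValidationError("no overlap between expression cells and annotation")
    sub_expr = expr.subset_cells(keep)
    sub_ann = CellAnnotation(
        ann.table[ann.table["cell_id"].isin(keep)]
        .set_index("cell_id").loc[keep].reset_index()
    )
    counts = sub_ann.counts()
    for cond in CONDITIONS:
        if counts.get(cond, 0) < min_per_condition:
            raise DataValidationError(
                f"fewer than {min_per_condition} cells left for condition {cond!r}"
            )
    if dropped:
        warnings.warn(f"align: dropped {len(dropped)} unannotated cells", stacklevel=2)
    return AlignedCohort(sub_expr, sub_ann, dropped)
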