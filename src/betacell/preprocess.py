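"""Log transform and the expressed-gene feature filter.

A gene is "expressed" in a cell when its raw value is at least
``min_expression`` (default 1 RPKM/TPM). A panel gene is kept as a
classification feature when the fraction of cells expressing it strictly
exceeds ``min_fraction``. The threshold can be given explicitly or derived
from the cohort's class balance: the minority-condition cell proportion
rounded down to the nearest 5% (194/472 healthy -> 0.411 -> 0.40;
99/270 T2D -> 0.367 -> 0.35; 96/264 T2D -> 0.364 -> 0.35).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .data_io import CellAnnotation, ExpressionMatrix, GenePanel

import numpy as np


def log2_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(x + pseudocount); zero-preserving when pseudocount=1.

    Refuses matrices already on the log2 scale (the scale marker travels with
    the matrix) and negative pseudocounts.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if expr.scale == "log2":
        raise ValueError("matrix is already log2-transformed")
    return ExpressionMatrix(np.log2(expr.data + pseudocount), scale="log2")


def derive_fraction(ann: CellAnnotation, step: float = 0.05) -> float:
    """Minority-condition cell proportion rounded down to the nearest ``step``."""
    counts = ann.counts()
    if len(counts) < 2:
        raise ValueError("both conditions must be present to derive a fraction")
    total = sum(counts.values())
    minority = min(counts.values())
    p = minority / total
    return math.floor(p / step + 1e-9) * step


@dataclass
class FilterSpec:
    """Expressed-gene filter parameters.

    fraction_rule="explicit" uses min_fraction as given;
    "minority_class" derives it from the annotation via derive_fraction.
    """

    min_expression: float = 1.0
    min_fraction: float = 0.35
    fraction_rule: str = "explicit"

    def __post_init__(self) -> None:
        if self.fraction_rule not in ("explicit", "minority_class"):
            raise ValueError(f"unknown fraction_rule {self.fraction_rule!r}")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")

    def resolve_fraction(self, ann: CellAnnotation | None) -> float:
        if self.fraction_rule == "minority_class":
            if ann is None:
                raise ValueError("minority_class rule needs a cell annotation")
            return derive_fraction(ann)
        return self.min_fraction


@dataclass
class FilterResult:
    kept: GenePanel
    fractions: pd.Series  # expressed-cell fraction per panel gene, panel order
    fraction_threshold: float
    missing_genes: list[str]


def filter_genes(expr: ExpressionMatrix, panel: GenePanel, spec: FilterSpec,
                 ann: CellAnnotation | None = None) -> FilterResult:
    """Keep panel genes expressed (raw value >= min_expression) in strictly
    more than the threshold fraction of all cells, both conditions pooled.

    Panel genes absent from the matrix count as fraction 0 and are reported,
    not fatal. Panel order is preserved in the result.
    """
    if expr.scale != "raw":
        raise ValueError("expressed-gene filter operates on the raw scale")
    threshold = spec.resolve_fraction(ann)
    fractions = {}
    missing = []
    for sym in panel.symbols:
        if sym in expr.data.index:
            fractions[sym] = float(
                (expr.data.loc[sym] >= spec.min_expression).mean()
            )
        else:
            fractions[sym] = 0.0
            missing.append(sym)
    if missing:
        warnings.warn(
            f"filter_genes: {len(missing)} panel genes absent from matrix: {missing}",
            stacklevel=2,
        )
    frac = pd.Series(fractions, name="expressed_fraction")
    kept_symbols = [s for s in panel.symbols if frac[s] > threshold]
    return FilterResult(
        kept=panel.subset(kept_symbols, name=f"{panel.name}_filtered"),
        fractions=frac,
        fraction_threshold=threshold,
        missing_genes=missing,
    )
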