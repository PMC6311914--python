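"""Log transform, threshold derivation from class balance, gene filter."""

import numpy as np
import pandas as pd
import pytest

from betacell.data_io import CellAnnotation, ExpressionMatrix, GenePanel
from betacell.preprocess import (FilterSpec, derive_fraction, filter_genes,
                                 log2_transform)


def make_ann(n_healthy: int, n_t2d: int) -> CellAnnotation:
    n = n_healthy + n_t2d
    return CellAnnotation(pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "donor_id": ["d"] * n,
        "condition": ["healthy"] * n_healthy + ["T2D"] * n_t2d,
        "cohort": ["x"] * n,
    }))


class TestLog2Transform:
    def test_values(self, small_expr):
        out = log2_transform(small_expr)
        assert out.scale == "log2"
        assert out.data.loc["INS", "c1"] == 0.0
        assert out.data.loc["INS", "c3"] == 2.0  # log2(3+1)
        assert out.data.loc["INS", "c6"] == 4.0  # log2(15+1)

    def test_double_transform_rejected(self, small_expr):
        once = log2_transform(small_expr)
        with pytest.raises(ValueError, match="already"):
            log2_transform(once)

    def test_negative_pseudocount_rejected(self, small_expr):
        with pytest.raises(ValueError):
            log2_transform(small_expr, pseudocount=-1)


class TestDeriveFraction:
    @pytest.mark.parametrize("n_h,n_t,expected", [
        (194, 278, 0.40),  # minority healthy, 0.411 -> 0.40
        (171, 99, 0.35),   # minority T2D, 0.367 -> 0.35
        (168, 96, 0.35),   # minority T2D, 0.364 -> 0.35
        (50, 50, 0.50),
    ])
    def test_minority_proportion_floored_to_5_percent(self, n_h, n_t, expected):
        assert derive_fraction(make_ann(n_h, n_t)) == pytest.approx(expected)

    def test_single_condition_rejected(self):
        ann = CellAnnotation(pd.DataFrame({
            "cell_id": ["a", "b"], "donor_id": ["d", "d"],
            "condition": ["healthy", "healthy"], "cohort": ["x", "x"]}))
        with pytest.raises(ValueError):
            derive_fraction(ann)


class TestFilterGenes:
    def make_matrix(self, rows: dict) -> ExpressionMatrix:
        return ExpressionMatrix(pd.DataFrame(
            rows, index=[f"c{i}" for i in range(10)]).T, scale="raw")

    def panel(self, genes) -> GenePanel:
        return GenePanel(pd.DataFrame(
            {"symbol": genes, "category": ["oxidative_stress"] * len(genes)}))

    def test_fraction_comparison(self):
        expr = self.make_matrix({
            "below": [5, 5, 5, 0, 0, 0, 0, 0, 0, 0],  # 3/10 expressed
            "above": [5, 5, 5, 5, 0, 0, 0, 0, 0, 0],  # 4/10 expressed
        })
        res = filter_genes(expr, self.panel(["below", "above"]),
                           FilterSpec(min_fraction=0.35))
        assert res.kept.symbols == ["above"]
        assert res.fractions["below"] == pytest.approx(0.3)

    def test_exact_boundary_dropped(self):
        values = [1.0] * 35 + [0.0] * 65
        expr = ExpressionMatrix(pd.DataFrame(
            {"g": values}, index=[f"c{i}" for i in range(100)]).T, scale="raw")
        res = filter_genes(expr, self.panel(["g"]), FilterSpec(min_fraction=0.35))
        assert res.kept.symbols == []  # 0.35 is not "more than 35%"

    def test_expression_threshold_is_inclusive(self):
        # "expressed" means raw value >= 1, so exactly 1 counts
        expr = self.make_matrix({"g": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]})
        res = filter_genes(expr, self.panel(["g"]), FilterSpec(min_fraction=0.35))
        assert res.fractions["g"] == pytest.approx(0.5)
        assert res.kept.symbols == ["g"]

    def test_missing_panel_gene_reported_not_fatal(self):
        expr = self.make_matrix({"g": [5] * 10})
        with pytest.warns(UserWarning, match="absent"):
            res = filter_genes(expr, self.panel(["g", "ghost"]),
                               FilterSpec(min_fraction=0.35))
        assert res.missing_genes == ["ghost"]
        assert res.fractions["ghost"] == 0.0
        assert res.kept.symbols == ["g"]

    def test_forced_silent_genes_are_dropped(self, rng):
        # 20 panel genes, 8 forced silent (all values < 1) -> exactly 12 kept
        genes = [f"g{i}" for i in range(20)]
        silent = set(genes[:8])
        rows = {g: (rng.uniform(0, 0.9, 10) if g in silent
                    else rng.uniform(2, 50, 10)) for g in genes}
        expr = ExpressionMatrix(pd.DataFrame(
            rows, index=[f"c{i}" for i in range(10)]).T, scale="raw")
        res = filter_genes(expr, self.panel(genes), FilterSpec(min_fraction=0.35))
        assert len(res.kept) == 12
        assert set(res.kept.symbols) == set(genes) - silent

    def test_idempotent_and_monotone_in_fraction(self, rng):
        genes = [f"g{i}" for i in range(15)]
        rows = {g: rng.uniform(0, 3, 10) for g in genes}
        expr = ExpressionMatrix(pd.DataFrame(
            rows, index=[f"c{i}" for i in range(10)]).T, scale="raw")
        panel = self.panel(genes)
        strict = filter_genes(expr, panel, FilterSpec(min_fraction=0.5))
        again = filter_genes(expr, strict.kept, FilterSpec(min_fraction=0.5))
        assert again.kept.symbols == strict.kept.symbols
        loose = filter_genes(expr, panel, FilterSpec(min_fraction=0.2))
        assert set(strict.kept.symbols) <= set(loose.kept.symbols)

    def test_requires_raw_scale(self, small_expr):
        from betacell.preprocess import log2_transform
        with pytest.raises(ValueError, match="raw"):
            filter_genes(log2_transform(small_expr), self.panel(["INS"]),
                         FilterSpec())

    def test_minority_rule_uses_annotation(self, small_expr, small_ann):
        spec = FilterSpec(fraction_rule="minority_class")
        res = filter_genes(small_expr, self.panel(["INS"]), spec, ann=small_ann)
        assert res.fraction_threshold == pytest.approx(0.50)
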