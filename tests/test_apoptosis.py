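"""Pathway PCA against an eigendecomposition oracle; MI screen semantics."""

import numpy as np
import pandas as pd
import pytest

from betacell.apoptosis import loading_screen, mi_screen, pca_project
from betacell.data_io import ExpressionMatrix, GenePanel
from betacell.infotheory import discretize, entropy


def panel_of(genes) -> GenePanel:
    return GenePanel(pd.DataFrame({"symbol": list(genes),
                                   "category": ["apoptosis_pathway"] * len(genes)}))


def random_log2_matrix(rng, n_genes=24, n_cells=60) -> ExpressionMatrix:
    data = pd.DataFrame(rng.normal(3, 1.5, size=(n_genes, n_cells)),
                        index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"c{i}" for i in range(n_cells)])
    return ExpressionMatrix(data, scale="log2")


def eigen_oracle(X):
    """Covariance eigendecomposition: top-2 loadings, scores, var fractions."""
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    loadings = v[:, :2]
    for k in range(2):
        if loadings[np.argmax(np.abs(loadings[:, k])), k] < 0:
            loadings[:, k] = -loadings[:, k]
    return loadings, Xc @ loadings, w[:2] / w.sum()


class TestPca:
    def test_matches_eigendecomposition_oracle(self, rng):
        expr = random_log2_matrix(rng)
        proj = pca_project(expr, panel_of(expr.gene_ids))
        loadings, scores, var = eigen_oracle(expr.data.to_numpy().T)
        np.testing.assert_allclose(proj.loadings.to_numpy(), loadings,
                                   atol=1e-8)
        np.testing.assert_allclose(proj.scores.to_numpy(), scores, atol=1e-8)
        np.testing.assert_allclose(proj.variance_fraction, var, atol=1e-10)

    def test_collinear_data_puts_all_variance_on_pc1(self, rng):
        t = rng.normal(0, 2, size=40)
        direction = rng.normal(size=6)
        data = pd.DataFrame(np.outer(direction, t),
                            index=[f"g{i}" for i in range(6)],
                            columns=[f"c{i}" for i in range(40)])
        proj = pca_project(ExpressionMatrix(data, scale="log2"),
                           panel_of(data.index))
        assert proj.variance_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_scores_are_centered(self, rng):
        proj = pca_project(random_log2_matrix(rng), panel_of([f"g{i}" for i in range(24)]))
        np.testing.assert_allclose(proj.scores.mean(axis=0), 0, atol=1e-10)

    def test_loadings_orthonormal(self, rng):
        proj = pca_project(random_log2_matrix(rng), panel_of([f"g{i}" for i in range(24)]))
        L = proj.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(2), atol=1e-10)

    def test_sign_convention(self, rng):
        proj = pca_project(random_log2_matrix(rng), panel_of([f"g{i}" for i in range(24)]))
        for col in ("PC1", "PC2"):
            v = proj.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_reconstruction_error_equals_discarded_variance(self, rng):
        expr = random_log2_matrix(rng, n_genes=6, n_cells=30)
        proj = pca_project(expr, panel_of(expr.gene_ids))
        X = expr.data.to_numpy().T
        Xc = X - X.mean(axis=0, keepdims=True)
        recon = proj.scores.to_numpy() @ proj.loadings.to_numpy().T
        resid = ((Xc - recon) ** 2).sum() / (X.shape[0] - 1)
        w = np.linalg.eigvalsh(Xc.T @ Xc / (X.shape[0] - 1))
        assert resid == pytest.approx(np.sort(w)[:-2].sum(), rel=1e-8)

    def test_too_few_cells_rejected(self, rng):
        data = pd.DataFrame(rng.normal(size=(4, 2)),
                            index=list("abcd"), columns=["c1", "c2"])
        with pytest.raises(ValueError, match="3 cells"):
            pca_project(ExpressionMatrix(data, scale="log2"), panel_of("abcd"))


class TestMiScreen:
    def test_gene_identical_to_tedecs_is_flagged_with_full_information(self, rng):
        tedecs = pd.Series(rng.integers(0, 40, size=80).astype(float),
                           index=[f"c{i}" for i in range(80)])
        mirror = np.log2(tedecs + 1.0)  # discretizes identically to TEDECs
        other = pd.Series(rng.normal(2, 1, size=80), index=tedecs.index)
        expr = ExpressionMatrix(pd.DataFrame({"MIRROR": mirror, "OTHER": other},
                                             index=tedecs.index).T,
                                scale="log2")
        screen = mi_screen(expr, panel_of(["MIRROR", "OTHER"]), tedecs)
        row = screen.set_index("gene").loc["MIRROR"]
        assert row["mutual_information"] == pytest.approx(
            entropy(discretize(np.log2(tedecs + 1))))
        assert bool(row["remarkable"])
        assert row["mi_rank"] == 1

    def test_missing_gene_reported(self, rng):
        tedecs = pd.Series(rng.uniform(0, 30, 10),
                           index=[f"c{i}" for i in range(10)])
        expr = ExpressionMatrix(pd.DataFrame(
            {"A": rng.normal(2, 1, 10)}, index=tedecs.index).T, scale="log2")
        screen = mi_screen(expr, panel_of(["A", "GONE"]), tedecs)
        assert bool(screen.set_index("gene").loc["GONE", "missing"])

    def test_rows_keep_panel_order(self, rng):
        tedecs = pd.Series(rng.uniform(0, 30, 20),
                           index=[f"c{i}" for i in range(20)])
        genes = ["Z", "A", "M"]
        expr = ExpressionMatrix(pd.DataFrame(
            rng.normal(2, 1, size=(3, 20)), index=genes,
            columns=tedecs.index), scale="log2")
        screen = mi_screen(expr, panel_of(genes), tedecs)
        assert screen["gene"].tolist() == genes


class TestLoadingScreen:
    def test_single_dominant_gene_ranks_first(self, rng):
        t = rng.normal(0, 3, size=50)
        data = pd.DataFrame(rng.normal(0, 0.05, size=(8, 50)),
                            index=[f"g{i}" for i in range(8)],
                            columns=[f"c{i}" for i in range(50)])
        data.iloc[3] += t  # only g3 varies
        proj = pca_project(ExpressionMatrix(data, scale="log2"),
                           panel_of(data.index))
        table = loading_screen(proj)
        assert table.iloc[0]["gene"] == "g3"
        assert table.iloc[0]["max_abs_loading"] == pytest.approx(1.0, abs=0.01)
        assert bool(table.iloc[0]["large"])

    def test_isotropic_data_has_no_dominant_loading(self, rng):
        proj = pca_project(random_log2_matrix(rng, n_genes=24, n_cells=200),
                           panel_of([f"g{i}" for i in range(24)]))
        table = loading_screen(proj)
        assert table.iloc[0]["max_abs_loading"] < 0.8
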