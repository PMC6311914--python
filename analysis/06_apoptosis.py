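"""Apoptosis analysis: TEDECs comparison, MI screen and pathway PCA.

On the cohort with T2D-specific stress, compares the TEDECs apoptosis proxy
between conditions, screens the 24 apoptosis-pathway genes by MI against
TEDECs (T2D cells, 0.6-bit line), and projects all cells onto the first two
principal components of the pathway genes. Writes
results/analysis/{apoptosis_screen,pca_loadings}.tsv.
"""

from pathlib import Path

import numpy as np

from betacell.apoptosis import loading_screen, mi_screen, pca_project
from betacell.assoc_stats import t_test
from betacell.data_io import load_apoptosis_panel
from betacell.experiments import _prepared_cohort

OUT = Path("results/analysis")
SEED = 0


def main() -> None:
    panel = load_apoptosis_panel()
    cohort, expr_log2, cond, scores = _prepared_cohort("dataset2_like", SEED)
    ted = scores.tedecs
    cmp = t_test(np.log2(ted[cond == "healthy"] + 1),
                 np.log2(ted[cond == "T2D"] + 1))
    print(f"TEDECs (log2): median {cmp.median_a:.2f} healthy vs "
          f"{cmp.median_b:.2f} T2D, p={cmp.p_value:.2g}")

    t2d = [c for c in cohort.expression.cell_ids if cond[c] == "T2D"]
    screen = mi_screen(expr_log2, panel, ted, cells=t2d)
    remarkable = screen[screen["remarkable"]].sort_values(
        "mutual_information", ascending=False)
    print(f"\n{len(remarkable)} genes above the 0.6-bit MI line (T2D cells):")
    for _, r in remarkable.iterrows():
        print(f"  {r['gene']:<8} MI={r['mutual_information']:.2f} bits")

    proj = pca_project(expr_log2, panel)
    loadings = loading_screen(proj)
    top = loadings.head(5)
    print(f"\nPC1/PC2 capture {proj.variance_fraction.sum():.0%} of the "
          f"pathway-gene variance; largest loadings:")
    for _, r in top.iterrows():
        print(f"  {r['gene']:<8} |loading|={r['max_abs_loading']:.2f}"
              + ("  *" if r["large"] else ""))

    OUT.mkdir(parents=True, exist_ok=True)
    screen.to_csv(OUT / "apoptosis_screen.tsv", sep="\t", index=False,
                  float_format="%.6g")
    loadings.to_csv(OUT / "pca_loadings.tsv", sep="\t", index=False,
                    float_format="%.6g")
    print(f"\nwrote {OUT / 'apoptosis_screen.tsv'} and {OUT / 'pca_loadings.tsv'}")


if __name__ == "__main__":
    main()
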