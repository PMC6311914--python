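# betacell

Stress-aware single-cell analysis of healthy and type-2-diabetic (T2D)
pancreatic β-cells.

## The problem

β-cells produce insulin, and their failure in T2D has two faces:
*dysfunction* (a cell expresses less INS than it should) and *deficit*
(cells are lost to apoptosis). Single-cell RNA-seq of donor islets lets
both be examined cell by cell, against the cellular stresses thought to
drive them — oxidative stress and endoplasmic-reticulum (ER) stress. This
package implements the full analysis chain for such data, for
computational biologists who want each step reusable, tested and
reproducible:

* **INS comparison** — healthy vs T2D per-cell log2 INS (Student's t-test).
* **Discrimination** — five classifiers (Bayes net, SVM, random forest,
  logistic regression, neural net) under leave-one-out cross-validation on
  a 45-gene stress/INS panel, scored by accuracy and F-measure
  (`F = 2·precision·recall/(precision+recall)`), after an expressed-gene
  filter whose threshold derives from the cohort's class balance.
* **Vulnerability** — cells binned Low/Medium/High along stress axes
  (JNK for oxidative, ATF6 for ER, CASP6 for caspase activity; thresholds
  4/8 and 2/4 on the log2 scale), then healthy-vs-T2D median INS compared
  within each bin.
* **MI attribution** — discrete mutual information
  `I(X;Y) = H(X) + H(Y) − H(X,Y)` in bits, on floor-discretized log2
  expression, ranking which stress factor carries most information about
  INS in T2D cells.
* **Apoptosis screen** — TEDECs (total expression of the death executioner
  caspases, CASP3+CASP6+CASP7) as an apoptosis proxy; MI of each of 24
  apoptosis-pathway genes against TEDECs (0.6-bit line), plus PCA of cells
  in pathway-gene space with loading inspection.
* **Donor summaries** — personalized per-donor INS/TEDECs medians and
  cross-group ordering flags.

Because the human datasets such analyses run on are access-restricted, the
package ships a **scenario generator** that simulates cohorts with the
three canonical stress regimes (low/low, healthy-low/T2D-high, high/high)
at realistic cohort sizes, with known latent ground truth — so every stage
is validated by parameter recovery, not by eyeballing.
See `docs/methods.md` for the models, parameters and limitations.

## Worked example

Attribute INS expression to stress factors on a simulated cohort whose T2D
cells carry high oxidative and ER stress, with INS coupled to oxidative
stress most strongly (coupling 1.5 vs 0.2):

```sh
python analysis/05_mi_attribution.py
```

```
dataset2_like (T2D cells, n=99):
  oxidative  H(INS)=3.19  H(factor)=3.50  H(joint)=5.37  MI=1.32 bits
  caspase    H(INS)=3.19  H(factor)=2.98  H(joint)=5.34  MI=0.84 bits
  ER         H(INS)=3.19  H(factor)=3.23  H(joint)=5.71  MI=0.72 bits
...
oxidative stress attains the largest MI with INS in 100% of 50 dataset2_like cohorts
```

Reading: the INS symbol distribution of the 99 T2D cells carries 3.19 bits
of entropy; knowing the cell's JNK (oxidative) level removes 1.32 of them —
nearly twice what the ER axis provides — and the ranking recovers the
generator's ground-truth coupling in every one of 50 independent cohorts.

The numbered scripts in `analysis/` walk the full study in order
(simulation → INS comparison → classification → vulnerability → MI
attribution → apoptosis → donors), each writing its tables under
`results/analysis/`. The same pipeline runs end-to-end on one cohort —
simulated or your own TSVs — via the CLI:

```sh
betacell simulate --scenario dataset2_like --seed 7 --out cohort/
betacell run --scenario dataset2_like --seed 7 --out run/
betacell run --expression expr.tsv --annotation cells.tsv --out run/
```

`run/` then contains one TSV per stage (ins_comparison, stress_scores,
classification_metrics, vulnerability, mi_attribution, apoptosis_screen,
pca_projection, pca_loadings, donor_summaries), each stamped with the
config hash; identical configs give byte-identical outputs.

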