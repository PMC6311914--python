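"""End-to-end orchestration of the analysis on one cohort.

``run_pipeline`` executes the stages in the order of the underlying study
design — INS comparison, stress scoring, classification, vulnerability
binning, MI attribution, apoptosis screen + PCA, donor summaries — and
writes one TSV per stage into the output directory, together with the fully
resolved configuration and a run log. Every table carries the configuration
hash in a leading comment line, so any table can be traced to the exact run
that produced it; given the same config (including seed) the output is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .apoptosis import loading_screen, mi_screen, pca_project
from .assoc_stats import t_test
from .classify import build_feature_table, evaluate_all, CLASSIFIER_KINDS
from .data_io import (align, load_apoptosis_panel, load_stress_panel,
                      read_annotation, read_expression, read_gene_panel)
from .donors import summarize_donors
from .infotheory import mi_attribution
from .preprocess import FilterSpec, filter_genes, log2_transform
from .stress import (DEFAULT_THRESHOLDS, bin_stress, compute_stress_scores,
                     vulnerability_compare)
from .synthetic_data import scenario_config, simulate_cohort


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    # either a scenario name (simulated input) ...
    scenario: str | None = "dataset2_like"
    # ... or paths to user-supplied expression + metadata
    expression_path: str | None = None
    annotation_path: str | None = None
    expression_format: str = "tsv"
    stress_panel_path: str | None = None  # None = bundled 45-gene panel
    apoptosis_panel_path: str | None = None  # None = bundled 24-gene panel
    min_expression: float = 1.0
    fraction: str | float = "auto"  # "auto" = minority-class rule
    thresholds: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_THRESHOLDS.items()})
    mi_threshold: float = 0.6
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS
    mi_cells: str = "t2d"  # "t2d" or "all"
    seed: int = 0
    out_dir: str = "results/run"

    def validate(self) -> None:
        if self.scenario is None:
            if not self.expression_path or not self.annotation_path:
                raise ValueError(
                    "config needs either a scenario or both expression_path "
                    "and annotation_path")
        if isinstance(self.fraction, str) and self.fraction != "auto":
            raise ValueError("fraction must be 'auto' or a number")
        unknown = set(self.classifiers) - set(CLASSIFIER_KINDS)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")
        if self.mi_cells not in ("t2d", "all"):
            raise ValueError("mi_cells must be 't2d' or 'all'")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifiers"] = list(self.classifiers)
        return d

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.as_dict()
        d.pop("out_dir")
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.md5(payload).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, config_hash: str,
                 index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.8g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a pipeline output table (skipping the config-hash comment)."""
    return pd.read_csv(path, sep="\t", comment="#")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage on one cohort; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    log_lines: list[str] = [f"betacell {__version__} run, config_hash={chash}"]

    def log(msg: str) -> None:
        log_lines.append(msg)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - stage boundary
                (out / "INCOMPLETE").write_text(f"failed at stage {name}: {exc}\n")
                (out / "run.log").write_text("\n".join(log_lines) + "\n")
                raise PipelineError(name, exc) from exc
        return deco

    # ---- inputs ----------------------------------------------------------
    @stage("load")
    def cohort():
        if config.scenario is not None:
            sim = simulate_cohort(scenario_config(config.scenario,
                                                  seed=config.seed))
            log(f"simulated scenario {config.scenario} "
                f"({sim.expression.n_cells} cells, {sim.expression.n_genes} genes)")
            return align(sim.expression, sim.annotation)
        expr = read_expression(config.expression_path,
                               format=config.expression_format)
        ann = read_annotation(config.annotation_path)
        log(f"loaded {expr.n_cells} cells x {expr.n_genes} genes from "
            f"{config.expression_path}")
        return align(expr, ann)

    expr_raw = cohort.expression
    ann = cohort.annotation
    stress_panel = (read_gene_panel(config.stress_panel_path)
                    if config.stress_panel_path else load_stress_panel())
    apop_panel = (read_gene_panel(config.apoptosis_panel_path)
                  if config.apoptosis_panel_path else load_apoptosis_panel())
    expr_log2 = log2_transform(expr_raw)
    cond = ann.condition_of(expr_raw.cell_ids)
    t2d_cells = [c for c in expr_raw.cell_ids if cond[c] == "T2D"]

    # ---- INS comparison --------------------------------------------------
    @stage("ins_comparison")
    def _ins():
        ins = expr_log2.gene("INS")
        cmp = t_test(ins[cond == "healthy"], ins[cond == "T2D"])
        df = pd.DataFrame([{
            "gene": "INS",
            "median_healthy": cmp.median_a, "median_t2d": cmp.median_b,
            "mean_healthy": cmp.mean_a, "mean_t2d": cmp.mean_b,
            "t_statistic": cmp.t_statistic, "p_value": cmp.p_value,
            "significant": cmp.significant,
            "n_healthy": cmp.n_a, "n_t2d": cmp.n_b,
        }])
        _write_table(df, out / "ins_comparison.tsv", chash)
        log(f"INS healthy-vs-T2D: p={cmp.p_value:.3g}")
        return cmp

    # ---- stress scores ---------------------------------------------------
    @stage("stress_scores")
    def scores():
        s = compute_stress_scores(expr_raw, expr_log2)
        df = s.axes.copy()
        df.insert(0, "tedecs", s.tedecs)
        df.insert(0, "condition", cond)
        _write_table(df.rename_axis("cell_id"), out / "stress_scores.tsv",
                     chash, index=True)
        return s

    # ---- classification --------------------------------------------------
    @stage("classification")
    def _classify():
        spec = (FilterSpec(min_expression=config.min_expression,
                           fraction_rule="minority_class")
                if config.fraction == "auto" else
                FilterSpec(min_expression=config.min_expression,
                           min_fraction=float(config.fraction)))
        fres = filter_genes(expr_raw, stress_panel, spec, ann=ann)
        log(f"filter kept {len(fres.kept)}/{len(stress_panel)} genes at "
            f"fraction>{fres.fraction_threshold:.2f}")
        table = build_feature_table(expr_log2, ann, fres.kept.symbols,
                                    name="own")
        metrics = evaluate_all(table, kinds=tuple(config.classifiers),
                               seed=config.seed)
        _write_table(metrics, out / "classification_metrics.tsv", chash)
        kept = pd.DataFrame({"gene": fres.fractions.index,
                             "expressed_fraction": fres.fractions.to_numpy(),
                             "kept": [g in fres.kept.symbols
                                      for g in fres.fractions.index]})
        _write_table(kept, out / "gene_filter.tsv", chash)
        return metrics

    # ---- vulnerability ---------------------------------------------------
    @stage("vulnerability")
    def _vuln():
        ins = expr_log2.gene("INS")
        parts = []
        for axis, thr in config.thresholds.items():
            bins = bin_stress(scores.axes[axis], axis, tuple(thr))
            parts.append(vulnerability_compare(ins, bins, cond))
        df = pd.concat(parts, ignore_index=True)
        _write_table(df, out / "vulnerability.tsv", chash)
        return df

    # ---- MI attribution --------------------------------------------------
    @stage("mi_attribution")
    def _mi():
        cells = t2d_cells if config.mi_cells == "t2d" else expr_raw.cell_ids
        ins = expr_log2.gene("INS").loc[cells]
        factors = {axis: scores.axes.loc[cells, axis]
                   for axis in scores.axes.columns}
        df = mi_attribution(ins, factors)
        _write_table(df, out / "mi_attribution.tsv", chash)
        top = df.iloc[0]
        log(f"MI attribution ({config.mi_cells} cells): top factor "
            f"{top['factor']} at {top['mutual_information']:.3f} bits")
        return df

    # ---- apoptosis screen + PCA -----------------------------------------
    @stage("apoptosis")
    def _apop():
        parts = []
        for group, cells in (("T2D", t2d_cells),
                             ("healthy", [c for c in expr_raw.cell_ids
                                          if cond[c] == "healthy"])):
            sub = mi_screen(expr_log2, apop_panel, scores.tedecs, cells=cells,
                            threshold=config.mi_threshold)
            sub.insert(0, "group", group)
            parts.append(sub)
        screen = pd.concat(parts, ignore_index=True)
        _write_table(screen, out / "apoptosis_screen.tsv", chash)
        proj = pca_project(expr_log2, apop_panel)
        scores_df = proj.scores.copy()
        scores_df.insert(0, "condition", cond)
        _write_table(scores_df.rename_axis("cell_id"),
                     out / "pca_projection.tsv", chash, index=True)
        load = loading_screen(proj)
        load["variance_fraction_pc1"] = proj.variance_fraction[0]
        load["variance_fraction_pc2"] = proj.variance_fraction[1]
        _write_table(load, out / "pca_loadings.tsv", chash)
        return screen

    # ---- donors ----------------------------------------------------------
    @stage("donors")
    def _donors():
        table, flags = summarize_donors(expr_log2.gene("INS"), scores.tedecs,
                                        ann)
        for k, v in flags.items():
            table[k] = v
        _write_table(table, out / "donor_summaries.tsv", chash)
        log(f"donor flags: {flags}")
        return table

    (out / "run_config.json").write_text(
        json.dumps({"config": config.as_dict(), "config_hash": chash},
                   indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    incomplete = out / "INCOMPLETE"
    if incomplete.exists():
        incomplete.unlink()
    return out
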