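"""Scenario-based generator of healthy/T2D beta-cell expression cohorts.

The generator emulates the three regimes observed across published islet
scRNA-seq cohorts, so every downstream stage (filtering, classification,
stress binning, MI attribution, apoptosis screening, donor summaries) can be
exercised and validated against known ground truth without any downloads:

* ``dataset1_like`` — low cellular stress in both conditions, no
  stress-INS coupling: healthy and T2D cells are statistically
  indistinguishable (the null regime).
* ``dataset2_like`` — low stress in healthy cells, high oxidative and ER
  stress in T2D cells, with stress-coupled INS suppression in T2D only.
* ``dataset3_like`` — high stress in both conditions; only T2D cells suffer
  INS suppression (the "vulnerability" regime: healthy cells tolerate the
  same stress).

Generative model (all on the log2-expression scale, per cell i of donor j):

    S_ox, S_er        ~ max(0, Normal(condition stress level, stress_sd))
    stress-panel gene g: baseline_g + loading_g * S_axis(g) + d_j + eps
    executioner caspase: baseline + 0.5*S_ox + 0.5*S_er + d_j + eps
    INS:                baseline_INS + d_j + eps
                         - [coupling_oxid*S_ox + coupling_er*S_er]  (T2D only)
    apoptosis driver:   baseline + driver_coupling*(0.5*S_ox+0.5*S_er) + d_j + eps
    other panel genes:  baseline + d_j + eps
    background gene:    baseline + eps

with d_j ~ Normal(0, donor_sd) a per-donor intercept and
eps ~ Normal(0, noise_sd) per cell and gene. Log2 values are clamped at 0
and converted to the raw scale as 2^x - 1.

Dropout is expression-dependent, as in full-length scRNA-seq protocols and
the standard simulators of them: each entry is zeroed independently with
probability ``dropout_rate * sigmoid((DROPOUT_MIDPOINT - x) / DROPOUT_SHAPE)``
where x is the entry's log2 value, so ``dropout_rate`` is the rate for
weakly expressed entries while strongly expressed transcripts (INS, or a
stress gene under high stress) essentially never drop to zero. Everything
is deterministic given ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (CellAnnotation, ExpressionMatrix, GenePanel,
                      load_apoptosis_panel, load_stress_panel,
                      write_annotation, write_expression)

INS_BASELINE = 14.0
INS_RELATED_BASELINE = 6.0
CASPASE_BASELINE = 0.5
CASPASE_WEIGHT_OX = 0.5
CASPASE_WEIGHT_ER = 0.5
APOPTOSIS_BASELINE = 3.0
DRIVER_BASELINE = 1.5
# dropout probability decays logistically with log2 expression: half the
# maximal rate at DROPOUT_MIDPOINT, negligible ~4 log2 units above it
DROPOUT_MIDPOINT = 4.0
DROPOUT_SHAPE = 1.0

SCENARIO_NAMES = ("dataset1_like", "dataset2_like", "dataset3_like", "custom")


@dataclass
class ScenarioConfig:
    """Parameters of one simulated cohort.

    Stress levels are mean latent stress on the log2-expression scale;
    couplings are INS-suppression slopes applied to T2D cells only. Preset
    scenarios fix exact per-condition cell totals (``n_cells_healthy`` /
    ``n_cells_t2d``) matching the published cohort compositions; when totals
    are None, per-donor cell counts are Poisson(cells_per_donor_mean), min 1.
    """

    scenario_name: str = "custom"
    n_donors_healthy: int = 6
    n_donors_t2d: int = 4
    cells_per_donor_mean: float = 30.0
    n_cells_healthy: int | None = None
    n_cells_t2d: int | None = None
    stress_ox_healthy: float = 2.0
    stress_ox_t2d: float = 6.5
    stress_er_healthy: float = 1.0
    stress_er_t2d: float = 3.5
    stress_sd: float = 2.5
    coupling_oxid: float = 1.5
    coupling_er: float = 0.2
    donor_sd: float = 0.5
    noise_sd: float = 0.8
    dropout_rate: float = 0.1
    apoptosis_drivers: tuple[str, ...] = ("TNFR1", "BAX", "CAPN1")
    driver_coupling: float = 1.5
    n_background: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario_name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.scenario_name!r}")
        numeric = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)
                   if f.name not in ("scenario_name", "apoptosis_drivers",
                                     "n_cells_healthy", "n_cells_t2d")}
        for name, value in numeric.items():
            if not math.isfinite(float(value)):
                raise ValueError(f"config field {name} is not finite: {value!r}")
        if self.n_donors_healthy < 1 or self.n_donors_t2d < 1:
            raise ValueError("need at least one donor per condition")
        if self.cells_per_donor_mean <= 0:
            raise ValueError("cells_per_donor_mean must be positive")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        for name in ("stress_ox_healthy", "stress_ox_t2d", "stress_er_healthy",
                     "stress_er_t2d", "stress_sd", "coupling_oxid",
                     "coupling_er", "donor_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("n_cells_healthy", "n_cells_t2d"):
            v = getattr(self, name)
            if v is not None and v < self_min_cells(getattr(
                    self, "n_donors_healthy" if "healthy" in name else "n_donors_t2d")):
                raise ValueError(f"{name} too small for the donor count")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["apoptosis_drivers"] = list(self.apoptosis_drivers)
        return d


def self_min_cells(n_donors: int) -> int:
    # every donor contributes at least one cell
    return n_donors


#: preset cohort compositions and stress regimes (donor and cell counts follow
#: the published three-cohort study design: 472 = 194 healthy + 278 T2D cells,
#: 270 = 171 + 99, 264 = 168 + 96)
PRESETS: dict[str, dict] = {
    "dataset1_like": dict(
        n_donors_healthy=12, n_donors_t2d=6,
        n_cells_healthy=194, n_cells_t2d=278,
        stress_ox_healthy=1.0, stress_ox_t2d=1.0,
        stress_er_healthy=1.0, stress_er_t2d=1.0,
        coupling_oxid=0.0, coupling_er=0.0,
    ),
    "dataset2_like": dict(
        n_donors_healthy=6, n_donors_t2d=4,
        n_cells_healthy=171, n_cells_t2d=99,
        stress_ox_healthy=2.0, stress_ox_t2d=6.5,
        stress_er_healthy=1.0, stress_er_t2d=3.5,
        coupling_oxid=1.5, coupling_er=0.2,
    ),
    "dataset3_like": dict(
        n_donors_healthy=5, n_donors_t2d=3,
        n_cells_healthy=168, n_cells_t2d=96,
        stress_ox_healthy=6.5, stress_ox_t2d=6.5,
        stress_er_healthy=3.5, stress_er_t2d=3.5,
        coupling_oxid=1.5, coupling_er=0.2,
    ),
}


def scenario_config(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Build a ScenarioConfig from a named preset, with optional overrides."""
    if name == "custom":
        return ScenarioConfig(scenario_name="custom", seed=seed, **overrides)
    if name not in PRESETS:
        raise ValueError(f"unknown scenario {name!r}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return ScenarioConfig(scenario_name=name, seed=seed, **params)


@dataclass
class SyntheticCohort:
    """A simulated cohort plus the latent ground truth used to generate it."""

    expression: ExpressionMatrix  # raw scale, genes x cells
    annotation: CellAnnotation
    truth: pd.DataFrame  # per cell: latents, donor effect, pre-dropout INS
    config: ScenarioConfig


def _gene_baselines(stress_panel: GenePanel, apoptosis_panel: GenePanel,
                    config: ScenarioConfig):
    """Deterministic per-gene baselines and stress loadings.

    Representative axis genes (JNK, ATF6) carry loading 1.0 so that the
    canonical bin thresholds line up with the latent stress scale; the other
    panel genes get loadings spread over [0.6, 1.2] for heterogeneity.
    """
    baselines: dict[str, float] = {}
    loadings: dict[str, tuple[str, float]] = {}  # gene -> (axis, loading)

    for category, axis, rep in (("ER_stress", "er", "ATF6"),
                                ("oxidative_stress", "ox", "JNK")):
        genes = stress_panel.category(category)
        spread = np.linspace(0.6, 1.2, num=len(genes))
        for g, w in zip(genes, spread):
            baselines[g] = 1.0
            loadings[g] = (axis, 1.0 if g == rep else float(w))
    for g in stress_panel.category("executioner_caspase"):
        baselines[g] = CASPASE_BASELINE
    for g in stress_panel.category("INS_related"):
        baselines[g] = INS_BASELINE if g == "INS" else INS_RELATED_BASELINE
    for g in apoptosis_panel.symbols:
        if g in baselines:
            continue
        baselines[g] = (DRIVER_BASELINE if g in config.apoptosis_drivers
                        else APOPTOSIS_BASELINE)
    background = [f"BG{i:03d}" for i in range(1, config.n_background + 1)]
    for g, b in zip(background, np.linspace(0.5, 7.0, num=len(background))):
        baselines[g] = float(b)
    return baselines, loadings, background


def simulate_cohort(config: ScenarioConfig) -> SyntheticCohort:
    """Draw one cohort from the generative model; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    stress_panel = load_stress_panel()
    apoptosis_panel = load_apoptosis_panel()
    missing_drivers = [g for g in config.apoptosis_drivers
                       if g not in apoptosis_panel.symbols]
    if missing_drivers:
        raise ValueError(f"apoptosis drivers not in panel: {missing_drivers}")
    baselines, loadings, background = _gene_baselines(
        stress_panel, apoptosis_panel, config)
    caspases = stress_panel.category("executioner_caspase")
    apoptosis_extra = [g for g in apoptosis_panel.symbols
                       if g not in stress_panel.symbols]

    # ---- donors and cell allocation -------------------------------------
    donors, conditions, donor_of_cell = [], [], []
    for cond, n_donors, n_cells, prefix in (
            ("healthy", config.n_donors_healthy, config.n_cells_healthy, "H"),
            ("T2D", config.n_donors_t2d, config.n_cells_t2d, "T2D")):
        ids = [f"{prefix}{i}" for i in range(1, n_donors + 1)]
        donors.extend(ids)
        conditions.extend([cond] * n_donors)
        if n_cells is not None:
            # exact per-condition total: one guaranteed cell per donor, the
            # remainder multinomially distributed
            extra = rng.multinomial(n_cells - n_donors,
                                    np.full(n_donors, 1.0 / n_donors))
            counts = extra + 1
        else:
            counts = np.maximum(
                rng.poisson(config.cells_per_donor_mean, size=n_donors), 1)
        for d, k in zip(ids, counts):
            donor_of_cell.extend([d] * int(k))

    n = len(donor_of_cell)
    donor_index = {d: i for i, d in enumerate(donors)}
    donor_effects = rng.normal(0.0, config.donor_sd, size=len(donors))
    cond_of_donor = dict(zip(donors, conditions))
    cell_cond = np.array([cond_of_donor[d] for d in donor_of_cell])
    is_t2d = cell_cond == "T2D"
    d_eff = np.array([donor_effects[donor_index[d]] for d in donor_of_cell])

    # ---- latent stresses -------------------------------------------------
    mu_ox = np.where(is_t2d, config.stress_ox_t2d, config.stress_ox_healthy)
    mu_er = np.where(is_t2d, config.stress_er_t2d, config.stress_er_healthy)
    s_ox = np.maximum(rng.normal(mu_ox, config.stress_sd), 0.0)
    s_er = np.maximum(rng.normal(mu_er, config.stress_sd), 0.0)
    apop_latent = CASPASE_WEIGHT_OX * s_ox + CASPASE_WEIGHT_ER * s_er

    gene_order = (stress_panel.symbols + apoptosis_extra + background)
    log2_expr = np.empty((len(gene_order), n))
    noise = lambda: rng.normal(0.0, config.noise_sd, size=n)

    for gi, g in enumerate(gene_order):
        base = baselines[g]
        if g == "INS":
            x = base + d_eff + noise()
            x = x - np.where(is_t2d,
                             config.coupling_oxid * s_ox
                             + config.coupling_er * s_er, 0.0)
        elif g in loadings:
            axis, w = loadings[g]
            latent = s_ox if axis == "ox" else s_er
            x = base + w * latent + d_eff + noise()
        elif g in caspases:
            x = base + apop_latent + d_eff + noise()
        elif g in config.apoptosis_drivers:
            x = base + config.driver_coupling * apop_latent + d_eff + noise()
        elif g in apoptosis_extra:
            x = base + d_eff + noise()
        else:  # background: no donor structure
            x = base + noise()
        log2_expr[gi] = x

    log2_expr = np.maximum(log2_expr, 0.0)
    raw = np.exp2(log2_expr) - 1.0
    if config.dropout_rate > 0:
        p_drop = config.dropout_rate / (
            1.0 + np.exp((log2_expr - DROPOUT_MIDPOINT) / DROPOUT_SHAPE))
        keep = rng.random(raw.shape) >= p_drop
        raw = raw * keep

    cell_ids = [f"{config.scenario_name}_c{i:04d}" for i in range(1, n + 1)]
    expr = ExpressionMatrix(
        pd.DataFrame(raw, index=gene_order, columns=cell_ids), scale="raw")
    ann = CellAnnotation(pd.DataFrame({
        "cell_id": cell_ids,
        "donor_id": donor_of_cell,
        "condition": cell_cond,
        "cohort": config.scenario_name,
    }))
    truth = pd.DataFrame({
        "cell_id": cell_ids,
        "donor_id": donor_of_cell,
        "condition": cell_cond,
        "s_ox": s_ox,
        "s_er": s_er,
        "apoptosis_latent": apop_latent,
        "donor_effect": d_eff,
        "ins_suppression": np.where(
            is_t2d, config.coupling_oxid * s_ox + config.coupling_er * s_er, 0.0),
    })
    return SyntheticCohort(expression=expr, annotation=ann, truth=truth,
                           config=config)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path,
                 format: str = "tsv") -> dict[str, Path]:
    """Write expression, metadata, latent truth and config to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if format == "mtx":
        paths["expression"] = out / "matrix.mtx"
        write_expression(cohort.expression, paths["expression"], format="mtx")
    else:
        paths["expression"] = out / "expression.tsv"
        write_expression(cohort.expression, paths["expression"], format=format)
    paths["annotation"] = out / "cells.tsv"
    write_annotation(cohort.annotation, paths["annotation"])
    paths["truth"] = out / "truth.tsv"
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False,
                        float_format="%.8g")
    paths["config"] = out / "scenario_config.json"
    paths["config"].write_text(json.dumps(cohort.config.as_dict(), indent=2,
                                          sort_keys=True) + "\n")
    return paths
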