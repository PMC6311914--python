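"""Generator contracts: determinism, preset cohort structure, coupling
semantics and ground-truth completeness."""

import numpy as np
import pandas as pd
import pytest

from betacell.synthetic_data import (PRESETS, ScenarioConfig, scenario_config,
                                     simulate_cohort, write_cohort)


def corr(a, b) -> float:
    return float(np.corrcoef(np.asarray(a), np.asarray(b))[0, 1])


class TestConfig:
    def test_presets_cover_three_regimes(self):
        d1, d2, d3 = (PRESETS[f"dataset{i}_like"] for i in (1, 2, 3))
        # low/low, healthy-low T2D-high, high/high oxidative regimes
        assert d1["stress_ox_healthy"] == d1["stress_ox_t2d"] < d2["stress_ox_t2d"]
        assert d2["stress_ox_healthy"] < d2["stress_ox_t2d"]
        assert d3["stress_ox_healthy"] == d3["stress_ox_t2d"]
        assert d1["coupling_oxid"] == 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ScenarioConfig(noise_sd=float("nan"))

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(dropout_rate=-0.1)
        with pytest.raises(ValueError):
            ScenarioConfig(coupling_oxid=-1.0)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            scenario_config("dataset9_like")


class TestSimulation:
    def test_same_seed_identical_cohort(self):
        a = simulate_cohort(scenario_config("dataset2_like", seed=11))
        b = simulate_cohort(scenario_config("dataset2_like", seed=11))
        pd.testing.assert_frame_equal(a.expression.data, b.expression.data)
        pd.testing.assert_frame_equal(a.annotation.table, b.annotation.table)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self):
        a = simulate_cohort(scenario_config("dataset2_like", seed=1))
        b = simulate_cohort(scenario_config("dataset2_like", seed=2))
        assert not a.expression.data.equals(b.expression.data)

    @pytest.mark.parametrize("name,n_h,n_t,d_h,d_t", [
        ("dataset1_like", 194, 278, 12, 6),
        ("dataset2_like", 171, 99, 6, 4),
        ("dataset3_like", 168, 96, 5, 3),
    ])
    def test_preset_cohort_sizes(self, name, n_h, n_t, d_h, d_t):
        c = simulate_cohort(scenario_config(name, seed=3))
        counts = c.annotation.counts()
        assert counts["healthy"] == n_h
        assert counts["T2D"] == n_t
        donors = c.annotation.table.groupby("condition")["donor_id"].nunique()
        assert donors["healthy"] == d_h
        assert donors["T2D"] == d_t

    def test_every_donor_has_a_cell(self):
        c = simulate_cohort(scenario_config("dataset3_like", seed=5))
        per_donor = c.annotation.table["donor_id"].value_counts()
        assert (per_donor >= 1).all()
        assert len(per_donor) == 8

    def test_values_non_negative_and_dropout_exact_zero(self):
        c = simulate_cohort(scenario_config(
            "custom", seed=7, dropout_rate=0.6, noise_sd=0.5))
        vals = c.expression.data.to_numpy()
        assert (vals >= 0).all()
        assert (vals == 0).sum() > 0  # dropout produces exact zeros

    def test_zero_coupling_leaves_ins_independent_of_stress(self):
        # with no coupling and no dropout, INS should be uncorrelated with
        # any stress gene; average correlation over seeds ~ 0
        cors = []
        for seed in range(20):
            c = simulate_cohort(scenario_config(
                "dataset2_like", seed=seed, coupling_oxid=0.0,
                coupling_er=0.0, dropout_rate=0.0))
            ins = np.log2(c.expression.gene("INS") + 1)
            jnk = np.log2(c.expression.gene("JNK") + 1)
            cors.append(corr(ins, jnk))
        assert abs(np.mean(cors)) < 0.05

    def test_stress_gap_matches_configured_regime(self):
        c = simulate_cohort(scenario_config("dataset2_like", seed=9,
                                            dropout_rate=0.0))
        cond = c.annotation.condition_of(c.expression.cell_ids)
        jnk = np.log2(c.expression.gene("JNK") + 1)
        gap = (jnk[(cond == "T2D").to_numpy()].mean()
               - jnk[(cond == "healthy").to_numpy()].mean())
        configured = (PRESETS["dataset2_like"]["stress_ox_t2d"]
                      - PRESETS["dataset2_like"]["stress_ox_healthy"])
        # clamping at 0 compresses the healthy side a little
        assert gap == pytest.approx(configured, abs=1.0)

    def test_stronger_oxidative_coupling_lowers_t2d_ins_only(self):
        weak = simulate_cohort(scenario_config("dataset2_like", seed=13,
                                               coupling_oxid=0.5))
        strong = simulate_cohort(scenario_config("dataset2_like", seed=13,
                                                 coupling_oxid=2.5))
        for cohort in (weak, strong):
            cohort.ins = np.log2(cohort.expression.gene("INS") + 1)
            cohort.cond = cohort.annotation.condition_of(
                cohort.expression.cell_ids).to_numpy()
        assert (np.median(strong.ins[strong.cond == "T2D"])
                < np.median(weak.ins[weak.cond == "T2D"]))
        assert (np.median(strong.ins[strong.cond == "healthy"])
                == pytest.approx(np.median(weak.ins[weak.cond == "healthy"])))

    def test_truth_contains_all_latents(self):
        c = simulate_cohort(scenario_config("dataset2_like", seed=1))
        for col in ("cell_id", "donor_id", "condition", "s_ox", "s_er",
                    "apoptosis_latent", "donor_effect", "ins_suppression"):
            assert col in c.truth.columns
        healthy = c.truth[c.truth["condition"] == "healthy"]
        assert (healthy["ins_suppression"] == 0).all()
        assert (c.truth["s_ox"] >= 0).all()


class TestWriter:
    def test_round_trip_via_files(self, tmp_path):
        from betacell.data_io import read_annotation, read_expression
        c = simulate_cohort(scenario_config("custom", seed=2,
                                            cells_per_donor_mean=5.0,
                                            n_donors_healthy=2, n_donors_t2d=2))
        paths = write_cohort(c, tmp_path)
        expr = read_expression(paths["expression"])
        ann = read_annotation(paths["annotation"])
        assert expr.cell_ids == c.expression.cell_ids
        assert ann.cell_ids == c.annotation.cell_ids
        np.testing.assert_allclose(expr.data.to_numpy(),
                                   c.expression.data.to_numpy(), rtol=1e-6)
        assert paths["config"].exists() and paths["truth"].exists()
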