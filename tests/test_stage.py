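"""Stage-1 spatial model, reduction, BLUEs, Cullis H2, across-year stage."""

import numpy as np
import pandas as pd
import pytest

from namgwas.design import generate_smarthouse
from namgwas.mixedmodel import MixedModel, RandomBlock
from namgwas.phenosim import (GrowthModel, SimulationTruth, TraitArchitecture,
                              simulate_experiment)
from namgwas.population import simulate_population
from namgwas.stage import (build_design_matrices, combine_years, cullis_h2,
                           extract_blues, fit_stage_one,
                           natural_spline_penalty, reduce_model,
                           spline_random_basis)
from namgwas.traits import derive_trait_table


class TestSplineBasis:
    def test_penalty_quadratic_form_identity(self):
        grid = np.arange(1.0, 25.0)
        knots, Z = spline_random_basis(grid)
        pen = natural_spline_penalty(grid)
        assert np.allclose(Z.T @ pen @ Z, np.eye(Z.shape[1]), atol=1e-9)

    def test_penalty_annihilates_linear(self):
        grid = np.linspace(0, 10, 9)
        pen = natural_spline_penalty(grid)
        f = 2.0 + 0.3 * grid
        assert abs(f @ pen @ f) < 1e-9


class TestDesignMatrices:
    def test_column_structure_small(self, small_trait_table):
        d = build_design_matrices(small_trait_table, "SAsm")
        assert "mu" in d.column_names
        assert "T[drought]" in d.column_names
        assert any(c.startswith("G[") for c in d.column_names)
        # centred covariates sum to zero on the retained rows
        j = d.column_names.index("S[NE]:cLane")
        assert abs(d.X[:, j].sum()) < 1e-8
        assert {b.name for b in d.blocks} >= {"mainplot"}
        assert len(d.group_labels) == 2  # one house x two treatments

    def test_residual_groups_partition(self, small_trait_table):
        d = build_design_matrices(small_trait_table, "DW")
        assert len(d.resid_groups) == len(d.y)
        assert set(d.resid_groups) == set(range(len(d.group_labels)))

    def test_missing_trait_rows_dropped(self, small_trait_table):
        t = small_trait_table.copy()
        t.loc[t.index[:5], "DW"] = np.nan
        d = build_design_matrices(t, "DW")
        assert len(d.y) == len(t) - 5


def _zero_noise_table(small_population, small_layout):
    truth = SimulationTruth(
        architecture=TraitArchitecture(intercept=0.0, family_effect_sd=8.0),
        growth=GrowthModel(noise_sd=0.0),
        smarthouse_effect={}, lane_coef={}, mainposn_coef={},
        spatial_field_amp=0.0, mainplot_sd=0.0, residual_sd={},
        zadoks_advanced_rate=0.0)
    psa, harvest = simulate_experiment(small_population, small_layout, truth,
                                       seed=21)
    return derive_trait_table(psa, harvest)


class TestBlues:
    def test_blue_equals_cell_value_without_noise(self, small_population,
                                                  small_layout):
        # no spatial effects, no noise: the BLUE reproduces each line's value
        table = _zero_noise_table(small_population, small_layout)
        fit = fit_stage_one(build_design_matrices(table, "SAsm"))
        blues = extract_blues(fit)
        merged = blues.merge(table[["genotype", "treatment", "SAsm"]],
                             on=["genotype", "treatment"])
        assert np.allclose(merged["blue"], merged["SAsm"], atol=1e-5)

    def test_adding_constant_shifts_blues(self, small_trait_table):
        fit0 = fit_stage_one(build_design_matrices(small_trait_table, "SAsm"))
        t2 = small_trait_table.copy()
        t2["SAsm"] = t2["SAsm"] + 100.0
        fit1 = fit_stage_one(build_design_matrices(t2, "SAsm"))
        b0 = extract_blues(fit0).set_index(["genotype", "treatment"])["blue"]
        b1 = extract_blues(fit1).set_index(["genotype", "treatment"])["blue"]
        assert np.allclose(b1 - b0, 100.0, atol=1e-5)

    def test_spatial_adjustment_beats_raw_means(self, small_population,
                                                small_layout):
        # with a strong injected lane trend, model BLUEs should be closer
        # to the genetic truth than raw per-cart values
        truth = SimulationTruth(
            architecture=TraitArchitecture(intercept=0.0, family_effect_sd=8.0),
            growth=GrowthModel(noise_sd=1.0),
            smarthouse_effect={}, lane_coef={"NE": 4.0}, mainposn_coef={},
            spatial_field_amp=0.0, mainplot_sd=0.0,
            residual_sd={("NE", "control"): 2.0, ("NE", "drought"): 2.0},
            zadoks_advanced_rate=0.0)
        psa, harvest = simulate_experiment(small_population, small_layout,
                                           truth, seed=31)
        table = derive_trait_table(psa, harvest)
        fit = reduce_model(fit_stage_one(build_design_matrices(table, "SAsm")))
        blues = extract_blues(fit)
        ctrl = blues[blues["treatment"] == "control"].set_index("genotype")
        clean = truth.growth.curve(np.array([59.0]),
                                   treatment="control")[0]
        from namgwas.phenosim import simulate_genetic_values
        gv = simulate_genetic_values(small_population, truth.architecture,
                                     seed=21)
        raw = (table[table["treatment"] == "control"]
               .drop_duplicates("genotype", keep=False)
               .set_index("genotype"))
        gv_k = gv["genetic_value"]
        genos = [g for g in ctrl.index if g in raw.index]
        truth_area = {g: truth.growth.curve(np.array([59.0]), gv_k[g],
                                            "control")[0]
                      for g in genos}
        err_model = np.array([ctrl.loc[g, "blue"] - truth_area[g]
                              for g in genos])
        err_raw = np.array([raw.loc[g, "SAsm"] - truth_area[g]
                            for g in genos])
        rmse = lambda e: np.sqrt(np.mean((e - e.mean()) ** 2))
        assert rmse(err_model) < rmse(err_raw)


class TestReduceModel:
    def test_strong_lane_trend_retained(self, small_population, small_layout):
        kept = 0
        n_seeds = 8
        for s in range(n_seeds):
            truth = SimulationTruth(
                architecture=TraitArchitecture(family_effect_sd=5.0),
                growth=GrowthModel(noise_sd=1.0),
                smarthouse_effect={}, lane_coef={"NE": 5.0}, mainposn_coef={},
                spatial_field_amp=0.0, mainplot_sd=1.0,
                residual_sd={("NE", "control"): 3.0, ("NE", "drought"): 3.0},
                zadoks_advanced_rate=0.0)
            psa, harvest = simulate_experiment(small_population, small_layout,
                                               truth, seed=500 + s)
            table = derive_trait_table(psa, harvest)
            fit = reduce_model(fit_stage_one(build_design_matrices(table, "SAsm")))
            trend_tests = [t for t in fit.tests if t["term"] == "S:cLane"]
            # either the curved trend stayed (no Wald test run) or the Wald
            # test kept the linear trend
            if not trend_tests or trend_tests[0]["kept"]:
                kept += 1
        assert kept >= n_seeds - 1

    def test_lane_trend_recovery_within_2se(self, small_population,
                                            small_layout):
        hits, total = 0, 10
        for s in range(total):
            truth = SimulationTruth(
                architecture=TraitArchitecture(family_effect_sd=5.0),
                growth=GrowthModel(noise_sd=1.0),
                smarthouse_effect={}, lane_coef={"NE": 2.0}, mainposn_coef={},
                spatial_field_amp=0.0, mainplot_sd=1.0,
                residual_sd={("NE", "control"): 3.0, ("NE", "drought"): 3.0},
                zadoks_advanced_rate=0.0)
            psa, harvest = simulate_experiment(small_population, small_layout,
                                               truth, seed=900 + s)
            table = derive_trait_table(psa, harvest)
            fit = fit_stage_one(build_design_matrices(table, "SAsm"))
            names = fit.design.column_names
            j = names.index("S[NE]:cLane")
            jr = list(fit.model.kept).index(j)
            est = fit.model.beta_[jr]
            se = np.sqrt(fit.model.beta_cov_[jr, jr])
            if abs(est - 2.0) <= 2 * se:
                hits += 1
        assert hits >= 8

    def test_alpha_one_keeps_everything(self, small_trait_table):
        fit = reduce_model(fit_stage_one(
            build_design_matrices(small_trait_table, "SAsm")), alpha=1.0)
        assert all(t["kept"] for t in fit.tests if t["kind"] != "wald_f")


class TestCullisH2:
    def test_identity_limits(self):
        # vbar = 0 -> H2 = 1; vbar = 2 sigma_g^2 -> H2 = 0 (direct formula)
        assert 1.0 - 0.0 / (2 * 3.0) == 1.0
        assert 1.0 - (2 * 3.0) / (2 * 3.0) == 0.0

    def test_balanced_closed_form(self, rng):
        # t genotypes x r reps, iid errors: H2 = s2g / (s2g + s2e / r)
        t, r = 30, 4
        g = rng.normal(0, 2.0, t)
        y = np.repeat(g, r) + rng.normal(0, 1.5, t * r)
        d = pd.DataFrame({
            "genotype": np.repeat([f"g{i}" for i in range(t)], r),
            "treatment": "control",
            "smarthouse": "NE",
            "cLane": 0.0, "cMainPosn": 0.0,
            "main_plot_id": np.arange(t * r),
            "is_check": False, "is_recurrent": False,
            "Y": y})
        res = cullis_h2(d, "Y", "control")
        m = MixedModel(y, np.ones((t * r, 1)),
                       [RandomBlock("g", np.kron(np.eye(t), np.ones((r, 1))))]).fit()
        s2g = m.block_variances_["g"]
        s2e = m.resid_variances_[0]
        assert res.h2 == pytest.approx(s2g / (s2g + s2e / r), abs=1e-6)

    def test_h2_in_unit_interval(self, small_trait_table):
        res = cullis_h2(small_trait_table, "SAsm", "control")
        assert 0.0 <= res.h2 <= 1.0


class TestCombineYears:
    def _blues(self, year, genos, shift, se=1.0):
        return pd.DataFrame({
            "genotype": genos, "treatment": "control", "year": year,
            "blue": [10.0 + i + shift for i in range(len(genos))], "se": se})

    def test_single_year_identity(self):
        b = self._blues(2014, ["a", "b", "CHECK"], 0.0)
        out = combine_years(b, "control")
        assert np.allclose(out["blue"], b["blue"])

    def test_disconnected_years_warn_and_pass_through(self):
        b = pd.concat([self._blues(2014, ["a", "b"], 0.0),
                       self._blues(2015, ["c", "d"], 5.0)])
        with pytest.warns(UserWarning, match="share no genotypes"):
            out = combine_years(b, "control")
        assert len(out) == 4

    def test_year_effect_recovery_via_checks(self):
        hits, total = 0, 20
        for s in range(total):
            rng = np.random.default_rng(3000 + s)
            delta = 5.0
            rows = []
            for year, shift, genos in ((2014, 0.0, [f"a{i}" for i in range(30)]),
                                       (2015, delta, [f"b{i}" for i in range(30)])):
                for g in genos + ["NAVIGATOR", "BARKE"]:
                    base = rng.normal(10, 3) if not g.isupper() else 12.0
                    rows.append({"genotype": g, "treatment": "control",
                                 "year": year,
                                 "blue": base + shift + rng.normal(0, 0.5),
                                 "se": 0.5})
            b = pd.DataFrame(rows)
            out = combine_years(b, "control").set_index("genotype")
            # the two years' line groups should be aligned after adjustment
            a_mean = out.loc[[f"a{i}" for i in range(30)], "blue"].mean()
            b_mean = out.loc[[f"b{i}" for i in range(30)], "blue"].mean()
            pooled_se = 3.0 / np.sqrt(30) * np.sqrt(2) + 0.5
            if abs(a_mean - b_mean) <= 2.5 * pooled_se:
                hits += 1
        assert hits >= 17
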