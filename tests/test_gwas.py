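"""MAF filter, model-A regression, stepwise selection, CV scan, effects."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f as f_dist, kstest

from namgwas.genmap import GeneticMap, simulate_map
from namgwas.gwas import (GwasConfig, cross_validated_scan,
                          estimate_parent_effects, fit_model_a, maf_filter,
                          minor_allele_frequencies, select_cofactors,
                          variance_explained)
from namgwas.phenosim import TraitArchitecture, simulate_genetic_values
from namgwas.population import Genotypes, simulate_population


def _toy_genotypes(dosage_cols: dict, families=None) -> Genotypes:
    frame = pd.DataFrame(dosage_cols, dtype=float)
    frame.index = [f"L{i}" for i in range(len(frame))]
    fam = pd.Series(families if families is not None else "F01",
                    index=frame.index)
    return Genotypes(frame, fam)


def _flat_map(snp_ids, spacing=10.0) -> GeneticMap:
    per = int(np.ceil(len(snp_ids) / 7))
    rows = []
    for i, s in enumerate(snp_ids):
        rows.append((s, f"{i // per + 1}H", (i % per) * spacing))
    return GeneticMap(pd.DataFrame(rows, columns=["snp_id", "chromosome",
                                                  "position"]))


class TestMafFilter:
    def test_monomorphic_removed(self):
        g = _toy_genotypes({"a": [0] * 10, "b": [0, 2] * 5})
        out = maf_filter(g, 0.01)
        assert list(out.snp_ids) == ["b"]

    def test_single_het_in_100_removed_at_1_percent(self):
        col = [0.0] * 100
        col[3] = 1.0
        g = _toy_genotypes({"rare": col, "common": [0, 2] * 50})
        assert minor_allele_frequencies(g)["rare"] == pytest.approx(0.005)
        out = maf_filter(g, 0.01)
        assert "rare" not in out.snp_ids

    def test_threshold_zero_keeps_polymorphic(self):
        col = [0.0] * 100
        col[3] = 1.0
        g = _toy_genotypes({"rare": col, "mono": [0.0] * 100})
        out = maf_filter(g, 0.0)
        assert list(out.snp_ids) == ["rare"]

    def test_all_missing_dropped_with_warning(self):
        g = _toy_genotypes({"gone": [np.nan] * 10, "b": [0, 2] * 5})
        with pytest.warns(UserWarning, match="all-missing"):
            out = maf_filter(g, 0.01)
        assert "gone" not in out.snp_ids


class TestModelA:
    def test_exact_linear_relation(self, rng):
        snp = rng.integers(0, 3, 200).astype(float)
        res = fit_model_a(3.0 * snp, snp)
        assert res["coef"] == pytest.approx(3.0)
        assert res["r2"] == pytest.approx(1.0)
        assert res["p"] < 1e-12

    def test_collinear_snp_flagged(self, rng):
        snp = rng.integers(0, 3, 100).astype(float)
        res = fit_model_a(rng.normal(size=100), snp, cofactors=snp[:, None])
        assert res["collinear"]
        assert res["p"] == 1.0

    def test_null_p_values_uniform(self):
        # marginal-F p-values under the null are U(0,1)
        rng = np.random.default_rng(42)
        pvals = []
        snp = rng.integers(0, 3, 200).astype(float)
        cof = rng.integers(0, 3, (200, 2)).astype(float)
        for _ in range(400):
            y = rng.normal(size=200)
            pvals.append(fit_model_a(y, snp, cof)["p"])
        assert kstest(pvals, "uniform").pvalue > 0.01


def brute_force_stable_sets(y, G, alpha):
    """Enumerate subsets that satisfy the stepwise stopping criterion:
    every member significant given the rest, no outsider significant."""
    snps = list(G.columns)
    stable = []
    for k in range(len(snps) + 1):
        for subset in itertools.combinations(snps, k):
            inside = list(subset)
            ok = True
            for s in inside:
                others = [t for t in inside if t != s]
                res = fit_model_a(y, G[s].to_numpy(),
                                  G[others].to_numpy() if others else None)
                if res["p"] >= alpha:
                    ok = False
                    break
            if not ok:
                continue
            for s in snps:
                if s in inside:
                    continue
                res = fit_model_a(y, G[s].to_numpy(),
                                  G[inside].to_numpy() if inside else None)
                if res["p"] < alpha:
                    ok = False
                    break
            if ok:
                stable.append(set(subset))
    return stable


class TestStepwise:
    def test_exact_signal_selects_only_that_snp(self, rng):
        n = 200
        G = pd.DataFrame(rng.integers(0, 3, (n, 10)).astype(float),
                         columns=[f"s{i}" for i in range(10)])
        gmap = _flat_map(G.columns)
        y = G["s7"].to_numpy()
        sel = select_cofactors(y, G, gmap, alpha=0.001)
        assert sel == ["s7"]

    def test_matches_brute_force_stable_set(self):
        agree, unique_cases = 0, 0
        n_instances = 20
        for s in range(n_instances):
            rng = np.random.default_rng(7000 + s)
            n, m = 120, 6
            G = pd.DataFrame(rng.integers(0, 3, (n, m)).astype(float),
                             columns=[f"s{i}" for i in range(m)])
            gmap = _flat_map(G.columns)
            beta = np.zeros(m)
            beta[rng.integers(0, m)] = 0.8
            y = G.to_numpy() @ beta + rng.normal(size=n)
            sel = set(select_cofactors(y, G, gmap, alpha=0.001))
            stable = brute_force_stable_sets(y, G, 0.001)
            assert sel in stable
            if len(stable) == 1:
                unique_cases += 1
                agree += sel == stable[0]
        assert unique_cases >= n_instances // 2
        assert agree == unique_cases

    def test_pure_noise_selects_almost_nothing(self):
        counts = []
        for s in range(30):
            rng = np.random.default_rng(8000 + s)
            G = pd.DataFrame(rng.integers(0, 3, (400, 50)).astype(float),
                             columns=[f"s{i}" for i in range(50)])
            gmap = _flat_map(G.columns)
            y = rng.normal(size=400)
            counts.append(len(select_cofactors(y, G, gmap, alpha=0.001)))
        assert np.mean(counts) < 1.0

    def test_column_order_invariance(self, rng):
        n, m = 150, 8
        G = pd.DataFrame(rng.integers(0, 3, (n, m)).astype(float),
                         columns=[f"s{i}" for i in range(m)])
        gmap = _flat_map(G.columns)
        y = G["s2"].to_numpy() * 0.9 + rng.normal(size=n)
        sel1 = select_cofactors(y, G, gmap)
        sel2 = select_cofactors(y, G[list(reversed(G.columns))], gmap)
        assert set(sel1) == set(sel2)


@pytest.fixture(scope="module")
def scan_setup():
    gmap = simulate_map(15, 150.0, seed=70)
    pop = simulate_population(gmap, [30] * 5, seed=71,
                              allow_any_family_count=True)
    snp = pop.snp_ids[40]
    arch = TraitArchitecture(qtl={snp: 2.0}, intercept=10.0)
    gv = simulate_genetic_values(pop, arch, seed=72)
    rng = np.random.default_rng(73)
    nam = pop.nam_lines()
    y = gv.loc[nam, "genetic_value"] + rng.normal(0, 0.8, len(nam))
    return gmap, pop, snp, y


class TestCrossValidatedScan:
    def test_run_bookkeeping(self, scan_setup):
        gmap, pop, snp, y = scan_setup
        cfg = GwasConfig(seed=74)
        res = cross_validated_scan(y, pop, gmap, cfg)
        assert len(res.run_selections) == 100
        assert cfg.n_runs == 100
        # fold conservation: folds partition the lines within each repeat
        for rep in range(cfg.repeats):
            runs = [r for r in res.run_selections if r["repeat"] == rep]
            assert len(runs) == cfg.folds

    def test_strong_qtl_detected_every_run(self, scan_setup):
        gmap, pop, snp, y = scan_setup
        res = cross_validated_scan(y, pop, gmap, GwasConfig(seed=75))
        mapt = gmap.table.set_index("snp_id")
        chrom = mapt.at[snp, "chromosome"]
        w = np.floor(mapt.at[snp, "position"] / 5.0) * 5.0
        wc = res.window_counts
        hit = wc[(wc["chromosome"] == chrom)
                 & (wc["window_start_cM"] == w)]["count"]
        assert int(hit.iloc[0]) == 100

    def test_determinism(self, scan_setup):
        gmap, pop, snp, y = scan_setup
        a = cross_validated_scan(y, pop, gmap, GwasConfig(seed=76))
        b = cross_validated_scan(y, pop, gmap, GwasConfig(seed=76))
        pd.testing.assert_series_equal(a.detection_counts, b.detection_counts)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GwasConfig(maf_threshold=0.6)
        with pytest.raises(ValueError):
            GwasConfig(detection_threshold=101)
        with pytest.raises(ValueError):
            GwasConfig(folds=1)


class TestParentEffects:
    def test_uniform_effect_recovered_everywhere(self, small_map):
        pop = simulate_population(small_map, [40, 40, 40], seed=80,
                                  allow_any_family_count=True)
        snp = pop.snp_ids[5]
        arch = TraitArchitecture(qtl={snp: 0.66}, intercept=5.0)
        gv = simulate_genetic_values(pop, arch, seed=81)
        y = gv.loc[pop.nam_lines(), "genetic_value"]
        eff = estimate_parent_effects(y, pop, [snp])
        segregating = eff["effect"].dropna()
        assert np.allclose(segregating, 1.32, atol=1e-8)

    def test_family_specific_effect(self, small_map):
        pop = simulate_population(small_map, [50, 50, 50], seed=82,
                                  allow_any_family_count=True)
        snp = pop.snp_ids[12]
        arch = TraitArchitecture(qtl={snp: {"F01": 0.66, "F02": 0.0,
                                            "F03": 0.0}})
        gv = simulate_genetic_values(pop, arch, seed=83)
        y = gv.loc[pop.nam_lines(), "genetic_value"]
        eff = estimate_parent_effects(y, pop, [snp]).set_index("family")
        assert eff.loc["F01", "effect"] == pytest.approx(1.32, abs=1e-8)
        assert eff.loc["F02", "effect"] == pytest.approx(0.0, abs=1e-8)

    def test_monomorphic_family_missing(self):
        dosage = {"q": [0, 1, 2, 1, 0, 0, 0, 0]}
        fams = ["F01"] * 4 + ["F02"] * 4
        g = _toy_genotypes(dosage, fams)
        y = pd.Series(g.dosage["q"].to_numpy(), index=g.dosage.index)
        eff = estimate_parent_effects(y, g, ["q"])
        assert set(eff["family"]) == {"F01"}


class TestVarianceExplained:
    def test_single_qtl_share_equals_total(self, rng):
        g = _toy_genotypes({"q": rng.integers(0, 3, 100).astype(float)})
        y = pd.Series(2.0 * g.dosage["q"] + rng.normal(0, 1, 100),
                      index=g.dosage.index)
        total, shares = variance_explained(y, g, ["q"])
        assert shares["q"] == pytest.approx(total)

    def test_correlated_qtl_shares_bounded(self):
        for s in range(5):
            rng = np.random.default_rng(9000 + s)
            base = rng.integers(0, 3, 150).astype(float)
            g = _toy_genotypes({
                "a": base,
                "b": np.clip(base + rng.integers(-1, 2, 150), 0, 2).astype(float),
                "c": rng.integers(0, 3, 150).astype(float)})
            y = pd.Series(base + 0.5 * g.dosage["c"] + rng.normal(0, 1, 150),
                          index=g.dosage.index)
            total, shares = variance_explained(y, g, ["a", "b", "c"])
            assert (shares >= 0).all()
            assert shares.sum() <= total + 1e-9

    def test_orthogonal_qtl_shares_sum_to_total(self):
        # orthogonal regressors: leave-one-out shares add up exactly
        n = 64
        a = np.tile([0.0, 2.0], n // 2)
        b = np.repeat([0.0, 2.0], n // 2)
        g = _toy_genotypes({"a": a, "b": b})
        rng = np.random.default_rng(1)
        y = pd.Series(a + 0.5 * b, index=g.dosage.index)
        total, shares = variance_explained(y, g, ["a", "b"])
        assert shares.sum() == pytest.approx(total, abs=1e-9)
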