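"""Mixed-model scan: GRM construction, REML, GLS oracles, regions, a/d."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rfi_integrate import synthetic_data as syn
from rfi_integrate.mlm_gwas import (
    GRM,
    compute_grm,
    define_qtl_regions,
    estimate_genotype_class_effects,
    fit_variance_components,
    genomic_inflation,
    run_scan,
    variance_explained,
)

from conftest import make_genotypes


def cg_design(table):
    dummies = pd.get_dummies(table.data["cg"]).to_numpy(float)
    return np.column_stack([np.ones(len(table)), dummies[:, 1:]])


def simulate_trait(n, m, sigma_a2, sigma_e2, seed, n_groups=5):
    g = syn.simulate_genotypes(n, m, seed=seed)
    truth = syn.SimulationTruth(sigma_a2=sigma_a2, sigma_e2=sigma_e2,
                                seed=seed + 10_000)
    table, y = syn.simulate_feedlot_phenotypes(g, truth, n_groups=n_groups)
    return g, cg_design(table), y


class TestComputeGrm:
    def test_vanraden_hand_example(self):
        g = make_genotypes([[0], [2]])
        grm = compute_grm(g)
        np.testing.assert_allclose(grm.values, [[2, -2], [-2, 2]])

    def test_duplicated_samples_have_identical_rows(self):
        g = make_genotypes([[0, 1, 2, 1], [0, 1, 2, 1], [2, 0, 1, 0]])
        grm = compute_grm(g)
        np.testing.assert_allclose(grm.values[0], grm.values[1])

    def test_mean_diagonal_near_one_under_hwe(self):
        g = syn.simulate_genotypes(200, 5000, ld_block_size=1, seed=1)
        grm = compute_grm(g)
        assert 0.95 <= grm.values.diagonal().mean() <= 1.05

    def test_symmetric_and_finite(self):
        g = syn.simulate_genotypes(50, 200, missing_rate=0.05, seed=2)
        grm = compute_grm(g)
        assert np.isfinite(grm.values).all()
        np.testing.assert_allclose(grm.values, grm.values.T)

    def test_all_monomorphic_rejected(self):
        g = make_genotypes([[2, 2], [2, 2], [2, 2]])
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(g)


class TestVarianceComponents:
    def test_null_trait_gives_small_h2(self):
        low = 0
        for seed in range(8):
            g, X, y = simulate_trait(400, 800, 0.0, 1.0, seed=seed)
            vc = fit_variance_components(y, X, compute_grm(g))
            low += vc.h2 < 0.1
        assert low >= 7

    def test_h2_half_recovered(self):
        ests = []
        for seed in range(6):
            g, X, y = simulate_trait(500, 2000, 1.0, 1.0, seed=100 + seed)
            vc = fit_variance_components(y, X, compute_grm(g))
            ests.append(vc.h2)
        assert abs(np.mean(ests) - 0.5) < 0.08

    def test_identity_grm_flags_boundary(self):
        rng = np.random.default_rng(3)
        n = 100
        y = rng.normal(size=n)
        grm = GRM(np.eye(n), [f"s{i}" for i in range(n)])
        vc = fit_variance_components(y, np.ones((n, 1)), grm)
        # sigma_a2 and sigma_e2 are unidentifiable; optimizer parks at a
        # bound and says so
        assert vc.at_bound

    def test_deterministic(self):
        g, X, y = simulate_trait(200, 400, 0.5, 0.5, seed=4)
        grm = compute_grm(g)
        a = fit_variance_components(y, X, grm)
        b = fit_variance_components(y, X, grm)
        assert a.h2 == b.h2


class TestRunScan:
    def test_reduces_to_ols_when_no_genetic_variance(self):
        from rfi_integrate.mlm_gwas import VarianceComponents
        g, X, y = simulate_trait(100, 50, 0.0, 1.0, seed=5)
        vc = VarianceComponents(sigma_a2=0.0, sigma_e2=1.0, h2=0.0,
                                reml_loglik=0.0)
        scan = run_scan(y, X, g, vc)
        # plain OLS oracle per SNP (normal reference on slope/se)
        D = g.dosages.copy()
        col = np.nanmean(D, axis=0)
        D[np.isnan(D)] = np.take(col, np.nonzero(np.isnan(D))[1])
        for j in range(g.n_snps):
            if np.isnan(scan.table.loc[j, "p"]):  # monomorphic SNP
                continue
            Xj = np.column_stack([X, D[:, j]])
            beta, res, *_ = np.linalg.lstsq(Xj, y, rcond=None)
            r = y - Xj @ beta
            sig2 = (r @ r) / (len(y) - Xj.shape[1])
            cov = sig2 * np.linalg.inv(Xj.T @ Xj)
            se = np.sqrt(cov[-1, -1])
            p = 2 * stats.norm.sf(abs(beta[-1] / se))
            assert abs(np.log10(scan.table.loc[j, "p"]) - np.log10(p)) < 1e-8

    def test_matches_dense_gls_oracle(self):
        g, X, y = simulate_trait(50, 5, 0.6, 0.4, seed=6)
        grm = compute_grm(g)
        vc = fit_variance_components(y, X, grm)
        scan = run_scan(y, X, g, vc, grm=grm)

        # brute force: explicit V^-1 GLS with per-SNP residual scale
        V = vc.h2 * (grm.values + 1e-6 * np.eye(50)) + (1 - vc.h2) * np.eye(50)
        Vi = np.linalg.inv(V)
        D = g.dosages
        for j in range(g.n_snps):
            Xj = np.column_stack([X, D[:, j]])
            A = Xj.T @ Vi @ Xj
            beta = np.linalg.solve(A, Xj.T @ Vi @ y)
            r = y - Xj @ beta
            sig2 = (r @ Vi @ r) / (50 - Xj.shape[1])
            se = np.sqrt(sig2 * np.linalg.inv(A)[-1, -1])
            assert scan.table.loc[j, "effect"] == pytest.approx(
                beta[-1], abs=1e-8)
            assert scan.table.loc[j, "se"] == pytest.approx(se, abs=1e-8)

    def test_planted_qtl_is_top_hit(self):
        hits = 0
        for seed in range(20):
            g = syn.simulate_genotypes(500, 1000, seed=seed)
            freqs = g.dosages.mean(axis=0) / 2
            # plant at the first comfortably polymorphic SNP near the middle
            qtl = 500 + int(np.argmax(
                (freqs[500:] > 0.2) & (freqs[500:] < 0.8)))
            dose = g.dosages[:, qtl]
            p = dose.mean() / 2
            # alpha sized so the QTL explains ~20% of trait variance
            alpha = np.sqrt(0.2 * 1.0 / (2 * p * (1 - p) * 0.8))
            truth = syn.SimulationTruth(
                qtl_snps=[(qtl, alpha, 0.0)], sigma_a2=0.3, sigma_e2=0.5,
                seed=seed + 10_000)
            table, y = syn.simulate_feedlot_phenotypes(g, truth)
            X = cg_design(table)
            grm = compute_grm(g)
            vc = fit_variance_components(y, X, grm)
            scan = run_scan(y, X, g, vc, grm=grm)
            top = scan.table["neglog10p"].idxmax()
            # the planted SNP or a same-LD-block neighbour must win
            hits += abs(top - qtl) < 20
        assert hits >= 19

    def test_scale_equivariance(self):
        g, X, y = simulate_trait(80, 40, 0.5, 0.5, seed=7)
        grm = compute_grm(g)
        vc = fit_variance_components(y, X, grm)
        scan1 = run_scan(y, X, g, vc, grm=grm)
        vc3 = fit_variance_components(3.0 * y, X, grm)
        scan3 = run_scan(3.0 * y, X, g, vc3, grm=grm)
        np.testing.assert_allclose(scan3.table["effect"],
                                   3.0 * scan1.table["effect"], rtol=1e-6)
        np.testing.assert_allclose(scan3.table["p"], scan1.table["p"],
                                   rtol=1e-6)

    def test_zero_variance_snp_is_na(self):
        g = make_genotypes([[1, 0], [1, 1], [1, 2], [1, 1]])
        from rfi_integrate.mlm_gwas import VarianceComponents
        vc = VarianceComponents(0.0, 1.0, 0.0, 0.0)
        grm = GRM(np.eye(4), g.sample_ids)
        y = np.array([0.1, -0.2, 0.3, 0.4])
        scan = run_scan(y, np.ones((4, 1)), g, vc, grm=grm)
        assert np.isnan(scan.table.loc[0, "effect"])
        assert np.isfinite(scan.table.loc[1, "effect"])


class TestGenomicInflation:
    def test_definition_at_half(self):
        assert genomic_inflation([0.5] * 7) == pytest.approx(1.0)

    def test_uniform_null_close_to_one(self):
        rng = np.random.default_rng(8)
        lam = genomic_inflation(rng.uniform(size=100_000))
        assert 0.97 <= lam <= 1.03

    def test_halving_p_increases_lambda(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.1, 1.0, size=1000)
        assert genomic_inflation(p / 2) > genomic_inflation(p)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation([])
        with pytest.raises(ValueError):
            genomic_inflation([0.5, 0.0])
        with pytest.raises(ValueError):
            genomic_inflation([1.5])


class TestVarianceExplained:
    def test_zero_effect(self):
        assert variance_explained(0.3, 0.0, 0.8) == 0.0

    @given(st.floats(0.01, 0.99), st.floats(-2, 2), st.floats(0.1, 5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_allele_frequency_fold_symmetry(self, p, alpha, s2):
        assert variance_explained(p, alpha, s2) == pytest.approx(
            variance_explained(1 - p, alpha, s2), rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(0.0, 0.1, 1.0)
        with pytest.raises(ValueError):
            variance_explained(0.3, 0.1, 0.0)


def scan_from_rows(rows):
    """rows: (snp_id, chrom, pos, neglog10p)."""
    from rfi_integrate.mlm_gwas import AssocScan, VarianceComponents
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "neglog10p"])
    df["maf"] = 0.3
    df["effect"] = 0.1
    df["se"] = 0.02
    df["p"] = 10.0 ** -df["neglog10p"]
    df["var_explained_pct"] = 1.0
    return AssocScan(df, 1.0, VarianceComponents(1.0, 1.0, 0.5, 0.0), {})


class TestQtlRegions:
    def test_two_snps_within_flank_merge(self):
        scan = scan_from_rows([("a", "20", 4_883_142, 8.98),
                               ("b", "20", 6_120_000, 4.6),
                               ("c", "20", 1_000, 1.0)])
        regions = define_qtl_regions(scan)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (4_883_142, 6_120_000)
        assert r.top_snp == "a"
        assert (r.flank_start, r.flank_end) == (3_883_142, 7_120_000)

    def test_single_snp_flank_clipped_at_zero(self):
        scan = scan_from_rows([("a", "1", 500_000, 5.0)])
        r = define_qtl_regions(scan)[0]
        assert (r.start, r.end) == (500_000, 500_000)
        assert (r.flank_start, r.flank_end) == (0, 1_500_000)

    def test_distant_snps_split(self):
        scan = scan_from_rows([("a", "1", 1_000_000, 5.0),
                               ("b", "1", 4_000_001, 5.0)])
        assert len(define_qtl_regions(scan)) == 2

    def test_order_independent(self):
        rows = [("a", "2", 3_000_000, 5.0), ("b", "1", 1_000_000, 6.0),
                ("c", "2", 3_500_000, 4.5), ("d", "1", 2_500_000, 4.4)]
        a = define_qtl_regions(scan_from_rows(rows))
        b = define_qtl_regions(scan_from_rows(rows[::-1]))
        assert [(r.chrom, r.start, r.end, r.top_snp) for r in a] == \
            [(r.chrom, r.start, r.end, r.top_snp) for r in b]

    def test_no_significant_snps_empty(self):
        scan = scan_from_rows([("a", "1", 100, 1.0)])
        assert define_qtl_regions(scan) == []

    def test_top_snp_tie_goes_to_smaller_position(self):
        scan = scan_from_rows([("a", "1", 2_000_000, 5.0),
                               ("b", "1", 1_000_000, 5.0)])
        assert define_qtl_regions(scan)[0].top_snp == "b"


class TestGenotypeClassEffects:
    def _fit(self, dose, y, n):
        from rfi_integrate.mlm_gwas import VarianceComponents
        vc = VarianceComponents(0.0, 1.0, 0.0, 0.0)
        grm = GRM(np.eye(n), [f"s{i}" for i in range(n)])
        return estimate_genotype_class_effects(
            y, np.ones((n, 1)), dose, vc, grm)

    def test_pure_additive_classes(self):
        dose = np.array([2.0] * 5 + [1.0] * 5 + [0.0] * 5)
        y = np.where(dose == 2, 1.0, np.where(dose == 1, 0.0, -1.0))
        eff = self._fit(dose, y, 15)
        assert eff.a == pytest.approx(1.0, abs=1e-8)
        assert eff.d == pytest.approx(0.0, abs=1e-8)

    def test_overdominance(self):
        dose = np.array([2.0] * 5 + [1.0] * 5 + [0.0] * 5)
        y = np.where(dose == 1, 1.0, 0.0)
        eff = self._fit(dose, y, 15)
        assert eff.a == pytest.approx(0.0, abs=1e-8)
        assert eff.d == pytest.approx(1.0, abs=1e-8)

    def test_noiseless_planted_a_and_d_recovered(self):
        rng = np.random.default_rng(10)
        n = 60
        dose = rng.integers(0, 3, size=n).astype(float)
        dose[:2], dose[2:4], dose[4:6] = 2.0, 1.0, 0.0  # all classes present
        zc = dose - dose.mean()
        y = 0.5 * zc + (-0.3) * (dose == 1.0)
        eff = self._fit(dose, y, n)
        assert eff.a == pytest.approx(0.5, abs=1e-8)
        assert eff.d == pytest.approx(-0.3, abs=1e-8)

    def test_missing_class_rejected(self):
        dose = np.array([2.0] * 8 + [1.0] * 7)
        y = np.zeros(15)
        with pytest.raises(ValueError, match="not estimable"):
            self._fit(dose, y, 15)

    def test_dominance_contrast_has_valid_p(self):
        rng = np.random.default_rng(11)
        n = 90
        dose = np.repeat([0.0, 1.0, 2.0], 30)
        y = 0.4 * dose + 0.6 * (dose == 1.0) + rng.normal(0, 0.2, n)
        eff = self._fit(dose, y, n)
        assert 0 < eff.d_p < 0.05
        assert eff.d == pytest.approx(0.6, abs=0.2)
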