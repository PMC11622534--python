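"""Kinship, REML, P3D marker scans, peak clumping and conditional classification."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from breedscan import gwas_lmm as gl
from breedscan import sim_panel as sp
from breedscan.panel_io import GenotypeMatrix

from conftest import random_genotypes


class TestKinship:
    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(0)
        G = random_genotypes(rng, 5, 8)
        K = gl.compute_kinship(G)
        X = G.imputed()
        p = X.mean(axis=0)
        denom = np.sum(p * (1 - p))
        for i in range(5):
            for j in range(5):
                kij = sum((X[i, k] - p[k]) * (X[j, k] - p[k]) for k in range(8)) / denom
                assert abs(K.values[i, j] - kij) < 1e-12

    def test_identical_lines_have_equal_self_and_cross_terms(self):
        rng = np.random.default_rng(1)
        G = random_genotypes(rng, 6, 20)
        G.calls[2] = G.calls[0]
        K = gl.compute_kinship(G)
        assert K.values[0, 2] == pytest.approx(K.values[0, 0], abs=1e-12)

    def test_row_sums_vanish_by_centering(self):
        rng = np.random.default_rng(2)
        G = random_genotypes(rng, 12, 40)
        K = gl.compute_kinship(G)
        np.testing.assert_allclose(K.values.sum(axis=1), 0.0, atol=1e-10)

    def test_monomorphic_only_matrix_is_error(self):
        calls = np.ones((4, 3))
        G = GenotypeMatrix(list("abcd"), [1] * 3, [10, 20, 30],
                           ["A"] * 3, ["T"] * 3, calls)
        with pytest.raises(ValueError, match="monomorphic"):
            gl.compute_kinship(G)


class TestNullModel:
    def test_identity_kinship_degenerate_ratio_handled_without_crash(self):
        # with K = I the variance ratio is unidentifiable (the REML profile is
        # exactly flat in lambda); the fit must still return finite results
        rng = np.random.default_rng(3)
        n = 40
        y = rng.normal(70, 3, n)
        K = gl.KinshipMatrix(np.eye(n), [f"L{i}" for i in range(n)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = gl.fit_null_model(y, np.ones((n, 1)), K)
        assert np.isfinite(fit.reml_loglik)
        assert np.isfinite(fit.lambda_v)
        # flat profile: the optimum is no better than any fixed ratio
        assert fit.reml_loglik == pytest.approx(
            gl.reml_loglik(1.0, y, np.ones((n, 1)), K), abs=1e-6)

    def test_optimum_beats_fixed_unit_ratio(self, default_panel):
        G = default_panel.genotypes
        K = gl.compute_kinship(G)
        rng = np.random.default_rng(4)
        y = 70 + K.values @ rng.normal(0, 1, G.n_lines) + rng.normal(0, 1, G.n_lines)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = gl.fit_null_model(y, np.ones((G.n_lines, 1)), K)
        assert fit.reml_loglik >= gl.reml_loglik(1.0, y, np.ones((G.n_lines, 1)), K) - 1e-6

    def test_variance_ratio_recovery(self, default_panel):
        # y simulated with sigma_g^2=2, sigma_e^2=1 on a realized kinship
        G = default_panel.genotypes.subset_lines(default_panel.genotypes.line_ids[:200])
        K = gl.compute_kinship(G)
        d, U = np.linalg.eigh(K.values)
        d = np.clip(d, 0, None)
        lams = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(30):
                rng = np.random.default_rng(seed)
                u = U @ (rng.normal(0, 1, 200) * np.sqrt(2 * d))
                y = 70 + u + rng.normal(0, 1, 200)
                lams.append(gl.fit_null_model(y, np.ones((200, 1)), K).lambda_v)
        assert 1.5 <= np.median(lams) <= 2.7

    def test_nonfinite_phenotype_is_error(self):
        K = gl.KinshipMatrix(np.eye(5), list("abcde"))
        with pytest.raises(ValueError, match="non-finite"):
            gl.fit_null_model(np.array([1, 2, np.nan, 4, 5.0]), np.ones((5, 1)), K)


class TestMarkerScan:
    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(5)
        G = random_genotypes(rng, 30, 40)
        y = 70 + 2 * G.calls[:, 7] + rng.normal(0, 2, 30)
        K = gl.KinshipMatrix(np.eye(30), list(G.line_ids))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = gl.marker_scan(y, G, K)
        for j in range(G.n_variants):
            x = G.calls[:, j]
            if np.std(x) == 0:
                continue
            lr = stats.linregress(x, y)
            ours = 10 ** (-res.table["neglog10p"].iloc[j])
            assert abs(ours - lr.pvalue) < 1e-8
            assert res.table["beta"].iloc[j] == pytest.approx(lr.slope, abs=1e-8)

    def test_marker_as_its_own_covariate_is_missing(self):
        rng = np.random.default_rng(6)
        G = random_genotypes(rng, 30, 10)
        y = rng.normal(70, 2, 30)
        K = gl.KinshipMatrix(np.eye(30), list(G.line_ids))
        cfg = gl.ScanConfig(covariates=[(1, int(G.pos[4]))])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = gl.marker_scan(y, G, K, cfg)
        assert np.isnan(res.table["neglog10p"].iloc[4])

    def test_absent_covariate_is_error(self):
        rng = np.random.default_rng(7)
        G = random_genotypes(rng, 20, 5)
        K = gl.KinshipMatrix(np.eye(20), list(G.line_ids))
        with pytest.raises(KeyError, match="9:12345"):
            gl.marker_scan(np.zeros(20) + 70.0, G, K,
                           gl.ScanConfig(covariates=["9:12345"]))

    def test_causal_marker_power(self):
        # beta = +8 d at n=250: the causal marker clears the suggestive threshold
        hits = 0
        n_rep = 12
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(n_rep):
                G, y, truth = sp.simulate_ld_panel(n_lines=250, n_neutral_per_chrom=50,
                                                   phi=0.0, seed=seed)
                K = gl.compute_kinship(G)
                res = gl.marker_scan(y, G, K)
                t = res.table
                row = t[(t["chrom"] == truth["causal"]["chrom"])
                        & (t["pos"] == truth["causal"]["pos"])]
                hits += int(row["neglog10p"].iloc[0] > 5.0)
        assert hits >= int(0.95 * n_rep)


class TestQqInflation:
    def _result_from_pvals(self, pvals):
        m = len(pvals)
        table = pd.DataFrame({"chrom": 1, "pos": np.arange(1, m + 1),
                              "beta": 0.0, "se": 1.0,
                              "neglog10p": -np.log10(pvals), "maf": 0.3})
        return gl.AssociationResult(table, 1.0, 100, gl.ScanConfig())

    def test_constant_half_pvalues_give_unit_inflation(self):
        lam, _ = gl.qq_inflation(self._result_from_pvals(np.full(500, 0.5)))
        assert lam == pytest.approx(1.0, abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 2000)
        lam1, _ = gl.qq_inflation(self._result_from_pvals(p))
        chi2 = stats.chi2.isf(p, 1)
        p2 = stats.chi2.sf(2 * chi2, 1)
        lam2, _ = gl.qq_inflation(self._result_from_pvals(p2))
        assert lam2 == pytest.approx(2 * lam1, rel=1e-10)

    def test_uniform_null_calibration(self):
        inside = 0
        for seed in range(10):
            p = np.random.default_rng(seed).uniform(0, 1, 10_000)
            lam, qq = gl.qq_inflation(self._result_from_pvals(p))
            inside += int(0.95 <= lam <= 1.05)
        assert inside >= 9

    def test_all_missing_is_error(self):
        res = self._result_from_pvals(np.full(200, 0.5))
        res.table["neglog10p"] = np.nan
        with pytest.raises(ValueError, match="no non-missing"):
            gl.qq_inflation(res)


class TestPeaks:
    def _toy_result(self, rows, year="2020"):
        table = pd.DataFrame(rows, columns=["chrom", "pos", "neglog10p"])
        table["beta"] = 1.0
        table["se"] = 0.1
        table["maf"] = 0.3
        return gl.AssociationResult(table, 1.0, 100, gl.ScanConfig())

    def _toy_G(self, chrom_pos, n=50, seed=0):
        rng = np.random.default_rng(seed)
        m = len(chrom_pos)
        calls = (rng.random((n, m)) < 0.5).astype(float)
        chrom = np.array([c for c, _ in chrom_pos])
        pos = np.array([p for _, p in chrom_pos])
        return GenotypeMatrix([f"L{i}" for i in range(n)], chrom, pos,
                              np.full(m, "A", object), np.full(m, "T", object), calls)

    def test_single_isolated_variant_is_its_own_peak(self):
        G = self._toy_G([(1, 1_000_000)])
        res = self._toy_result([(1, 1_000_000, 7.0)])
        peaks = gl.detect_peaks({"2020": res}, G)
        assert len(peaks) == 1
        assert peaks[0].seed == (1, 1_000_000)
        assert peaks[0].status == "consistent-across-years"

    def test_distant_loci_make_two_peaks(self):
        cp = [(1, 1_000_000), (1, 1_100_000), (1, 51_000_000)]
        G = self._toy_G(cp)
        res = self._toy_result([(1, 1_000_000, 9.0), (1, 1_100_000, 6.0),
                                (1, 51_000_000, 7.5)])
        peaks = gl.detect_peaks({"2020": res}, G)
        assert len(peaks) == 2
        assert peaks[0].start == 1_000_000 and peaks[0].end == 1_100_000

    def test_two_of_three_years_is_candidate_only(self):
        G = self._toy_G([(1, 1_000_000)])
        hot = self._toy_result([(1, 1_000_000, 7.0)])
        cold = self._toy_result([(1, 1_000_000, 2.0)])
        peaks = gl.detect_peaks({"2019": hot, "2020": hot, "2021": cold}, G)
        assert len(peaks) == 1
        assert peaks[0].status == "candidate"

    def test_variant_order_invariance(self):
        cp = [(1, 1_000_000), (2, 5_000_000), (1, 1_200_000)]
        rows = [(1, 1_000_000, 8.0), (2, 5_000_000, 6.0), (1, 1_200_000, 7.0)]
        G = self._toy_G(sorted(cp))
        p1 = gl.detect_peaks({"2020": self._toy_result(rows)}, G)
        p2 = gl.detect_peaks({"2020": self._toy_result(rows[::-1])}, G)
        assert [(p.chrom, p.start, p.end, p.seed) for p in p1] == \
               [(p.chrom, p.start, p.end, p.seed) for p in p2]

    def test_self_conditioning_is_ld_shadow(self):
        rng = np.random.default_rng(9)
        G = random_genotypes(rng, 60, 30)
        y = 70 + 5 * G.calls[:, 10] + rng.normal(0, 2, 60)
        K = gl.KinshipMatrix(np.eye(60), list(G.line_ids))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = gl.marker_scan(y, G, K)
            peaks = gl.detect_peaks({"2020": res}, G)
            assert len(peaks) >= 1
            target = peaks[0]
            out = gl.classify_peak(target, target, y, G, K)
        assert out.status == "LD-shadow"


class TestLd:
    def test_self_and_complement_r2_are_one(self):
        rng = np.random.default_rng(10)
        G = random_genotypes(rng, 40, 3)
        G.calls[:, 1] = 1 - G.calls[:, 0]
        a, b = (1, int(G.pos[0])), (1, int(G.pos[1]))
        assert gl.ld_r2(G, a, a) == pytest.approx(1.0)
        assert gl.ld_r2(G, a, b) == pytest.approx(1.0)

    def test_independent_variants_have_near_zero_r2(self):
        rng = np.random.default_rng(11)
        n = 10_000
        calls = (rng.random((n, 2)) < 0.5).astype(float)
        G = GenotypeMatrix([f"L{i}" for i in range(n)], [1, 1], [10, 20],
                           ["A", "A"], ["T", "T"], calls)
        assert gl.ld_r2(G, (1, 10), (1, 20)) < 0.01

    def test_zero_variance_gives_missing(self):
        calls = np.column_stack([np.ones(10), (np.arange(10) % 2).astype(float)])
        G = GenotypeMatrix([f"L{i}" for i in range(10)], [1, 1], [10, 20],
                           ["A", "A"], ["T", "T"], calls)
        assert np.isnan(gl.ld_r2(G, (1, 10), (1, 20)))
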