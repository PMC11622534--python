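"""Point-biserial/phi/partial correlations, Holm adjustment, and triage."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats

from breedscan import corr_partial as cp
from breedscan import sim_panel as sp


class TestPointBiserial:
    def test_hand_value(self):
        r, p = cp.point_biserial([0, 0, 1, 1], [1, 2, 3, 4])
        assert r == pytest.approx(0.8944, abs=1e-4)

    def test_equals_pearson_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(5, 40)
            code = (rng.random(n) < 0.5).astype(float)
            if code.min() == code.max():
                continue
            y = rng.normal(0, 1, n)
            r, p = cp.point_biserial(code, y)
            r_ref, p_ref = stats.pearsonr(code, y)
            assert abs(r - r_ref) < 1e-12 and abs(p - p_ref) < 1e-12

    def test_degenerate_inputs_warn_and_return_nan(self):
        with pytest.warns(UserWarning, match="degenerate"):
            r, p = cp.point_biserial([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(r)
        with pytest.warns(UserWarning, match="degenerate"):
            r, p = cp.point_biserial([0, 1, 0, 1], [2, 2, 2, 2])
        assert np.isnan(r)

    def test_pairwise_deletion(self):
        r, _ = cp.point_biserial([0, 0, 1, 1, np.nan], [1, 2, 3, 4, 100])
        assert r == pytest.approx(0.8944, abs=1e-4)


class TestPhi:
    def test_hand_value_from_2x2_table(self):
        a = np.repeat([1, 1, 0, 0], [40, 10, 10, 40])
        b = np.repeat([1, 0, 1, 0], [40, 10, 10, 40])
        assert cp.phi_coefficient(a, b) == pytest.approx(0.6, abs=1e-12)

    def test_equals_pearson_on_binary_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(6, 50)
            a = (rng.random(n) < 0.5).astype(float)
            b = (rng.random(n) < 0.5).astype(float)
            if a.min() == a.max() or b.min() == b.max():
                continue
            assert cp.phi_coefficient(a, b) == pytest.approx(
                stats.pearsonr(a, b)[0], abs=1e-12)

    def test_concordant_genes_and_degenerate_margin(self):
        a = np.array([0, 0, 1, 1, 1.0])
        assert cp.phi_coefficient(a, a) == pytest.approx(1.0)
        assert np.isnan(cp.phi_coefficient(a, np.ones(5)))

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(2)
        a = (rng.random(10_000) < 0.5).astype(float)
        b = (rng.random(10_000) < 0.5).astype(float)
        assert abs(cp.phi_coefficient(a, b)) < 0.05

    def test_matrix_diagonal_and_symmetry(self):
        rng = np.random.default_rng(3)
        codes = pd.DataFrame((rng.random((30, 4)) < 0.5).astype(float),
                             columns=list("wxyz"))
        M = cp.phi_matrix(codes)
        np.testing.assert_allclose(np.diag(M), 1.0)
        np.testing.assert_allclose(M.to_numpy(), M.to_numpy().T, atol=1e-15)


class TestPartial:
    def _panel(self, codes, y, signs=None):
        idx = [f"L{i}" for i in range(len(y))]
        codes = pd.DataFrame(codes, index=idx)
        y = pd.Series(np.asarray(y, float), index=idx)
        signs = signs if signs is not None else pd.Series(
            {g: 1 for g in codes.columns})
        return cp.CodedPanel.from_data(codes, y, signs)

    def test_matches_recursive_closed_form_two_genes(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n = 60
            x = (rng.random(n) < 0.5).astype(float)
            z = (rng.random(n) < np.where(x == 1, 0.7, 0.3)).astype(float)
            y = 2 * x - z + rng.normal(0, 1, n)
            if x.std() == 0 or z.std() == 0:
                continue
            panel = self._panel({"x": x, "z": z}, y)
            out = cp.partial_correlations(panel)
            r_xy = stats.pearsonr(x, y)[0]
            r_xz = stats.pearsonr(x, z)[0]
            r_zy = stats.pearsonr(z, y)[0]
            closed = (r_xy - r_xz * r_zy) / np.sqrt((1 - r_xz ** 2) * (1 - r_zy ** 2))
            assert out.loc["x", "partial_r"] == pytest.approx(closed, abs=1e-10)

    def test_three_variable_textbook_value(self):
        # r_xy=0.5, r_xz=r_yz=0.8 -> partial r_xy.z = (0.5-0.64)/0.36
        R = np.array([[1.0, 0.5, 0.8], [0.5, 1.0, 0.8], [0.8, 0.8, 1.0]])
        P = np.linalg.inv(R)
        r = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
        assert r == pytest.approx((0.5 - 0.64) / 0.36, abs=1e-12)

    def test_independent_conditioner_leaves_marginal_unchanged(self):
        x = np.tile([0.0, 1.0], 20)
        z = np.repeat([0.0, 1.0], 20)  # exactly orthogonal to x
        rng = np.random.default_rng(5)
        e = rng.normal(0, 1, 40)
        zc = z - z.mean()
        e = e - e.mean() - (e @ zc) / (zc @ zc) * zc  # residualize noise against z
        y = 3 * x + e  # now cov(z, y) = 0 exactly
        panel = self._panel({"x": x, "z": z}, y)
        out = cp.partial_correlations(panel)
        assert out.loc["x", "partial_r"] == pytest.approx(
            stats.pearsonr(x, panel.dth)[0], abs=1e-10)

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        n = 80
        codes = {g: (rng.random(n) < 0.5).astype(float) for g in ["a", "b", "c"]}
        y = 2 * codes["a"] - 3 * codes["b"] + rng.normal(0, 1, n)
        panel = self._panel(codes, y)
        out = cp.partial_correlations(panel)
        df = pd.concat([panel.codes, panel.dth.rename("y")], axis=1)
        for g in ["a", "b", "c"]:
            covar = [h for h in ["a", "b", "c"] if h != g]
            ref = pingouin.partial_corr(df, x=g, y="y", covar=covar)
            assert out.loc[g, "partial_r"] == pytest.approx(ref["r"].iloc[0], abs=1e-10)

    def test_singular_matrix_names_collinear_pair(self):
        x = np.tile([0.0, 1.0], 10)
        panel = self._panel({"a": x, "b": x.copy(), "c": 1 - x}, np.arange(20.0))
        with pytest.raises(ValueError, match=r"\('a', 'b'\)"):
            cp.partial_correlations(panel)

    def test_sample_size_guard(self):
        x = np.array([0, 1, 0, 1.0])
        panel = self._panel({"a": x, "b": x[::-1].copy()}, np.arange(4.0))
        with pytest.raises(ValueError, match="n > k\\+2"):
            cp.partial_correlations(panel)


class TestHolm:
    def test_hand_example_and_single_p(self):
        np.testing.assert_allclose(cp.holm_adjust([0.01, 0.02, 0.04]),
                                   [0.03, 0.04, 0.04], atol=1e-12)
        np.testing.assert_allclose(cp.holm_adjust([0.2]), [0.2], atol=1e-15)

    @settings(deadline=None, max_examples=200)
    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=12))
    def test_dominance_monotone_capped(self, pvals):
        adj = cp.holm_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_nan_passthrough_and_family_padding(self):
        adj = cp.holm_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        padded = cp.holm_adjust([0.01], m=6)
        assert padded[0] == pytest.approx(0.06, abs=1e-12)


class TestTriage:
    def _frames(self, rows):
        genes = list(rows)
        marg = pd.DataFrame({"marginal_r": [rows[g][0] for g in genes],
                             "marginal_p_holm": [rows[g][1] for g in genes],
                             "marginal_p": [rows[g][1] for g in genes]}, index=genes)
        part = pd.DataFrame({"partial_r": [rows[g][2] for g in genes],
                             "partial_p_holm": [rows[g][3] for g in genes],
                             "partial_p": [rows[g][4] for g in genes]}, index=genes)
        return marg, part

    def test_published_style_patterns(self):
        # anchor gene: both significant; borrowed signal: marginal-only + LD;
        # masked promoter: marginal ns positive, partial significant negative
        rows = {
            "anchor": (0.70, 1e-10, 0.72, 1e-12, 1e-13),
            "borrowed": (0.23, 0.004, 0.14, 0.30, 0.12),
            "masked": (0.15, 0.40, -0.29, 0.004, 0.001),
            "inert": (0.05, 0.90, 0.02, 0.95, 0.80),
        }
        marg, part = self._frames(rows)
        genes = list(rows)
        phis = pd.DataFrame(np.eye(4), index=genes, columns=genes)
        phis.loc["borrowed", "anchor"] = phis.loc["anchor", "borrowed"] = 0.30
        signs = pd.Series({"anchor": 1, "borrowed": 1, "masked": -1, "inert": 1})
        labels = cp.triage(marg, part, phis, signs)
        assert labels["anchor"] == "consistent"
        assert labels["borrowed"] == "type-I-candidate"
        assert labels["masked"] == "type-II-candidate"
        assert labels["inert"] == "null"

    def test_sign_flip_needs_nominal_partial_significance(self):
        rows = {"anchor": (0.70, 1e-10, 0.72, 1e-12, 1e-13),
                "noisy": (0.02, 0.90, -0.03, 0.90, 0.70)}
        marg, part = self._frames(rows)
        phis = pd.DataFrame(np.eye(2), index=list(rows), columns=list(rows))
        labels = cp.triage(marg, part, phis, pd.Series({"anchor": 1, "noisy": -1}))
        assert labels["noisy"] == "null"

    def test_marginal_only_without_ld_is_not_type_one(self):
        rows = {"anchor": (0.70, 1e-10, 0.72, 1e-12, 1e-13),
                "lone": (0.25, 0.01, 0.10, 0.60, 0.30)}
        marg, part = self._frames(rows)
        phis = pd.DataFrame(np.eye(2), index=list(rows), columns=list(rows))
        labels = cp.triage(marg, part, phis, pd.Series({"anchor": 1, "lone": 1}))
        assert labels["lone"] == "null"


class TestMaskedRecovery:
    def test_planted_confounding_recovered(self):
        """The Type II mechanism: a gated negative effect hidden by a positively
        correlated confounder is exposed by the partial correlation."""
        masked_hits = 0
        null_flags = 0
        nulls_total = 0
        n_rep = 25
        for seed in range(n_rep):
            codes, dth, signs, _ = sp.sample_coded_panel(seed=seed)
            panel = cp.CodedPanel.from_data(codes, dth, signs)
            rep = cp.correlation_report(panel)
            masked_hits += int(rep.loc["masked", "triage"] == "type-II-candidate")
            for g in rep.index:
                if g.startswith("null"):
                    nulls_total += 1
                    null_flags += int(rep.loc[g, "triage"] != "null")
        assert masked_hits >= int(0.9 * n_rep)
        assert null_flags / nulls_total <= 0.10

    def test_report_records_complete_case_n(self):
        codes, dth, signs, _ = sp.sample_coded_panel(seed=0)
        codes.iloc[0, 0] = np.nan
        panel = cp.CodedPanel.from_data(codes, dth, signs, year="2020")
        rep = cp.correlation_report(panel)
        assert rep.attrs["n"] == len(dth) - 1
        assert rep.attrs["year"] == "2020"
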