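"""Unit and property tests for the qPCR statistics module."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from conftest import make_ct_table
from ribodots import qpcr
from ribodots.simulate import default_panel, simulate_ct_table


# ---------------------------------------------------------------------------
# replicate aggregation
# ---------------------------------------------------------------------------

class TestAggregateReplicates:
    def test_mean_of_replicates(self):
        df = pd.DataFrame(
            {
                "gene": ["Arc"] * 3,
                "sample": ["s1"] * 3,
                "group": ["sleep"] * 3,
                "replicate": [1, 2, 3],
                "CT": [20.0, 20.2, 20.1],
            }
        )
        out = qpcr.aggregate_replicates(df)
        assert len(out) == 1
        assert out["CT"].iloc[0] == pytest.approx(20.1)
        assert out["ct_sd"].iloc[0] == pytest.approx(np.std([20.0, 20.2, 20.1], ddof=1))
        assert out["n_replicates"].iloc[0] == 3

    def test_single_replicate_passes_through(self):
        df = pd.DataFrame(
            {"gene": ["Arc"], "sample": ["s1"], "group": ["sleep"],
             "replicate": [1], "CT": [23.4]}
        )
        out = qpcr.aggregate_replicates(df)
        assert out["CT"].iloc[0] == 23.4
        assert np.isnan(out["ct_sd"].iloc[0])


# ---------------------------------------------------------------------------
# stability measures
# ---------------------------------------------------------------------------

def _random_panel(rng, n_genes=4, n_per_group=4):
    genes = [f"g{i}" for i in range(n_genes)]
    groups = ["sleep"] * n_per_group + ["SD"] * n_per_group
    values = {
        g: (rng.normal(20 + 2 * i, 1.0, size=len(groups))).tolist()
        for i, g in enumerate(genes)
    }
    return make_ct_table(values, groups), genes


def _oracle_two_way(table, genes):
    """Independent least-squares two-way decomposition per group.

    Within each group, fit CT ~ gene + sample by OLS on dummy variables;
    per-gene residual variance is bias-corrected by G/((n-1)(G-1)).  The
    intergroup difference is the gene-by-group interaction of the
    loading-corrected group means, obtained by double centering.
    """
    agg = table.groupby(["gene", "sample", "group"], as_index=False)["CT"].mean()
    piv = agg.pivot_table(index="gene", columns="sample", values="CT").reindex(genes)
    grp = agg.drop_duplicates("sample").set_index("sample")["group"]
    out_var, means = {}, {}
    for g in ("sleep", "SD"):
        cols = [s for s in piv.columns if grp[s] == g]
        sub = piv[cols].to_numpy()
        G, n = sub.shape
        y = sub.ravel()
        X = np.zeros((G * n, G + n))
        for gi in range(G):
            for si in range(n):
                X[gi * n + si, gi] = 1.0
                X[gi * n + si, G + si] = 1.0
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = (y - X @ beta).reshape(G, n)
        out_var[g] = (resid**2).sum(axis=1) * G / ((n - 1) * (G - 1))
        means[g] = sub.mean(axis=1)
    gm = np.column_stack([means["sleep"], means["SD"]])
    gm = gm - gm.mean(axis=0)
    inter = gm - gm.mean(axis=1, keepdims=True)
    d = {"sleep": inter[:, 0], "SD": inter[:, 1]}
    n_per = {g: (grp == g).sum() for g in ("sleep", "SD")}
    stability = 0.5 * sum(
        np.abs(d[g]) + np.sqrt(out_var[g] / n_per[g]) for g in ("sleep", "SD")
    )
    return out_var, d, stability


class TestModelBasedStability:
    def test_matches_brute_force_decomposition(self, rng):
        """Vectorized estimator equals an independent OLS oracle to 1e-9."""
        table, genes = _random_panel(rng, n_genes=4, n_per_group=4)
        got = qpcr.stability_model_based(table, genes)
        var_o, d_o, stab_o = _oracle_two_way(table, genes)
        np.testing.assert_allclose(
            got["intragroup_var"],
            0.5 * (var_o["sleep"] + var_o["SD"]),
            atol=1e-9,
        )
        np.testing.assert_allclose(got["intergroup_diff_SD"], d_o["SD"], atol=1e-9)
        np.testing.assert_allclose(got["stability"], stab_o, atol=1e-9)

    def test_perfectly_stable_gene_ranks_first(self):
        """Zero-variance, zero-deviation gene gets stability 0 and rank 1."""
        groups = ["sleep"] * 3 + ["SD"] * 3
        loading = [0.1, -0.2, 0.3, 0.0, 0.2, -0.1]
        values = {
            # stable: baseline + loading only
            "stable": [20 + l for l in loading],
            # up in SD / down in SD relative to panel: cancel each other
            "up": [22 + l + (0.5 if g == "SD" else 0) for l, g in zip(loading, groups)],
            "down": [24 + l - (0.5 if g == "SD" else 0) for l, g in zip(loading, groups)],
        }
        table = make_ct_table(values, groups)
        out = qpcr.stability_model_based(table, list(values))
        assert out.loc["stable", "stability"] == pytest.approx(0.0, abs=1e-12)
        assert out["stability"].idxmin() == "stable"

    def test_noise_increases_stability_value(self, rng):
        """Adding i.i.d. noise to one gene raises its stability value."""
        worse = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            table, genes = _random_panel(r, n_genes=4, n_per_group=5)
            base = qpcr.stability_model_based(table, genes).loc["g0", "stability"]
            noisy = table.copy()
            sel = noisy["gene"] == "g0"
            noisy.loc[sel, "CT"] += r.normal(0, 1.0, size=sel.sum())
            pert = qpcr.stability_model_based(noisy, genes).loc["g0", "stability"]
            worse += pert > base
        assert worse >= 18

    def test_too_few_genes_rejected(self, rng):
        table, genes = _random_panel(rng, n_genes=2)
        with pytest.raises(ValueError, match=">= 3"):
            qpcr.stability_model_based(table, genes)


class TestPairwiseM:
    def test_constant_difference_gives_zero_m(self):
        groups = ["sleep"] * 2 + ["SD"] * 2
        values = {"a": [20, 21, 22, 23], "b": [18, 19, 20, 21]}
        m = qpcr.stability_pairwise_m(make_ct_table(values, groups), ["a", "b"])
        assert m["a"] == pytest.approx(0.0, abs=1e-12)
        assert m["b"] == pytest.approx(0.0, abs=1e-12)

    def test_shift_invariance(self):
        groups = ["sleep"] * 3 + ["SD"] * 3
        rng = np.random.default_rng(0)
        values = {g: rng.normal(20, 1, 6).tolist() for g in "abc"}
        base = qpcr.stability_pairwise_m(make_ct_table(values, groups), list("abc"))
        values["b"] = [v + 5.0 for v in values["b"]]
        shifted = qpcr.stability_pairwise_m(make_ct_table(values, groups), list("abc"))
        np.testing.assert_allclose(base, shifted, atol=1e-12)

    def test_matches_hand_arithmetic_three_genes(self):
        """3-gene toy panel against explicitly computed pairwise SDs."""
        groups = ["sleep"] * 2 + ["SD"] * 2
        a = [20.0, 20.5, 21.0, 21.5]
        b = [18.0, 18.2, 18.4, 19.0]
        c = [25.0, 24.5, 25.5, 25.0]
        table = make_ct_table({"a": a, "b": b, "c": c}, groups)
        m = qpcr.stability_pairwise_m(table, ["a", "b", "c"])
        sd = lambda x, y: np.std(np.subtract(x, y), ddof=1)
        assert m["a"] == pytest.approx((sd(a, b) + sd(a, c)) / 2)
        assert m["b"] == pytest.approx((sd(b, a) + sd(b, c)) / 2)
        assert m["c"] == pytest.approx((sd(c, a) + sd(c, b)) / 2)


class TestRankAggregation:
    def test_unanimous_first(self):
        ranks = pd.DataFrame(
            {"m1": [1, 2, 3], "m2": [1, 3, 2]}, index=["a", "b", "c"]
        )
        agg = qpcr.stability_aggregate(ranks)
        assert agg["a"] == 1

    def test_tie_broken_by_first_method(self):
        """Geomean ties (1,4) vs (2,2) resolve by the first rank column."""
        ranks = pd.DataFrame({"m1": [1, 2], "m2": [4, 2]}, index=["a", "b"])
        agg = qpcr.stability_aggregate(ranks)
        assert agg["a"] == 1 and agg["b"] == 2

    def test_permutation_invariance(self):
        ranks = pd.DataFrame(
            {"m1": [3, 1, 2], "m2": [2, 1, 3]}, index=["a", "b", "c"]
        )
        agg = qpcr.stability_aggregate(ranks)
        perm = qpcr.stability_aggregate(ranks.loc[["c", "a", "b"]])
        assert (perm.reindex(agg.index) == agg).all()


class TestSelectPair:
    @staticmethod
    def _report(d, stab):
        genes = [f"g{i}" for i in range(len(d))]
        return pd.DataFrame(
            {
                "intergroup_diff": d,
                "stability": stab,
                "aggregated_rank": np.arange(1, len(d) + 1),
            },
            index=genes,
        )

    def test_countervailing_minimum_forced(self):
        rep = self._report([0.3, -0.3, 0.5], [0.1, 0.2, 0.3])
        assert qpcr.select_pair(rep, top_k=3) == ("g0", "g1")

    def test_tie_broken_by_stability(self):
        rep = self._report([0.2, 0.2, 0.2], [0.3, 0.1, 0.2])
        assert set(qpcr.select_pair(rep, top_k=3)) == {"g1", "g2"}

    def test_needs_two_candidates(self):
        rep = self._report([0.1], [0.1])
        with pytest.raises(ValueError):
            qpcr.select_pair(rep, top_k=1)


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

class TestFoldChangeConvert:
    # every printed pair of Table-style ratio/fold-change conversions the
    # convention reproduces at two decimals
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (0.98, -1.02),
            (0.90, -1.11),
            (0.87, -1.15),
            (0.82, -1.22),
            (1.02, 1.02),
            (0.97, -1.03),
            (1.00, 1.00),
        ],
    )
    def test_printed_conversions(self, ratio, expected):
        assert round(qpcr.fold_change_convert(ratio), 2) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            qpcr.fold_change_convert(0.0)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_antisymmetry_and_magnitude(self, r):
        f = qpcr.fold_change_convert(r)
        assert abs(f) >= 1.0
        if abs(r - 1.0) > 1e-9:
            assert qpcr.fold_change_convert(1.0 / r) == pytest.approx(-f, rel=1e-9)


class TestPairGroupRatio:
    def test_identical_groups_ratio_one(self):
        groups = ["sleep"] * 3 + ["SD"] * 3
        values = {"hk1": [20.0] * 6, "hk2": [22.0] * 6}
        ratio, fc = qpcr.pair_group_ratio(
            make_ct_table(values, groups), ("hk1", "hk2")
        )
        assert ratio == pytest.approx(1.0)
        assert fc == pytest.approx(1.0)

    def test_known_shift_gives_table_style_fold_change(self):
        """Pair-mean CT lower by 0.2 cycles in sleep -> ratio 0.87 -> -1.15."""
        groups = ["sleep"] * 3 + ["SD"] * 3
        values = {
            "hk1": [19.8, 19.8, 19.8, 20.0, 20.0, 20.0],
            "hk2": [21.8, 21.8, 21.8, 22.0, 22.0, 22.0],
        }
        ratio, fc = qpcr.pair_group_ratio(
            make_ct_table(values, groups), ("hk1", "hk2")
        )
        assert ratio == pytest.approx(2**-0.2, rel=1e-9)
        assert round(fc, 2) == -1.15

    def test_missing_sample_dropped_with_warning(self):
        groups = ["sleep"] * 2 + ["SD"] * 2
        table = make_ct_table(
            {"hk1": [20, 20, 20, 20], "hk2": [22, 22, 22, 22]}, groups
        )
        table = table[~((table["gene"] == "hk2") & (table["sample"] == "s1"))]
        with pytest.warns(UserWarning, match="dropping"):
            ratio, _ = qpcr.pair_group_ratio(table, ("hk1", "hk2"))
        assert ratio == pytest.approx(1.0)


class TestDeltaCt:
    def test_arithmetic(self):
        groups = ["sleep"] * 2 + ["SD"] * 2
        values = {"Arc": [25.0] * 4, "hk1": [20.0] * 4, "hk2": [22.0] * 4}
        out = qpcr.delta_ct(make_ct_table(values, groups), ("hk1", "hk2"))
        assert (out["dCT"] == 4.0).all()

    def test_target_equal_to_pair_mean_gives_zero(self):
        groups = ["sleep"] * 2 + ["SD"] * 2
        values = {"Arc": [21.0] * 4, "hk1": [20.0] * 4, "hk2": [22.0] * 4}
        out = qpcr.delta_ct(make_ct_table(values, groups), ("hk1", "hk2"))
        assert (out["dCT"] == 0.0).all()

    @given(st.floats(min_value=-5, max_value=5))
    def test_per_sample_shift_invariance(self, c):
        """Adding a constant to every CT of one sample leaves dCT unchanged."""
        groups = ["sleep"] * 2 + ["SD"] * 2
        values = {"Arc": [25.0, 24, 23, 22], "hk1": [20.0] * 4, "hk2": [22.0] * 4}
        table = make_ct_table(values, groups)
        base = qpcr.delta_ct(table, ("hk1", "hk2"))
        shifted = table.copy()
        shifted.loc[shifted["sample"] == "s2", "CT"] += c
        out = qpcr.delta_ct(shifted, ("hk1", "hk2"))
        np.testing.assert_allclose(out["dCT"], base["dCT"], atol=1e-9)


class TestDdct:
    def test_identical_groups(self):
        fc = qpcr.ddct_fold_change([5.0, 5.2, 4.8], [5.2, 5.0, 4.8])
        assert fc.ddct == pytest.approx(0.0)
        assert fc.log2_fc == pytest.approx(0.0)
        assert fc.fold_change == pytest.approx(1.0)

    def test_printed_group_means_identity(self):
        """Sleep dCT 5.16 +- 0.37 vs SD 3.90 +- 0.19 -> log2FC 1.26, SE 0.416."""
        fc = qpcr.ddct_from_summary(5.16, 0.37, 3.90, 0.19)
        assert fc.ddct == pytest.approx(-1.26)
        assert fc.log2_fc == pytest.approx(1.26)
        assert fc.se == pytest.approx(np.sqrt(0.37**2 + 0.19**2), rel=1e-12)
        assert fc.se == pytest.approx(0.416, abs=5e-4)
        assert fc.ratio == pytest.approx(2**1.26, rel=1e-12)

    def test_sign_consistency(self):
        up = qpcr.ddct_from_summary(5.0, 0.1, 4.0, 0.1)    # less cycles = more mRNA
        down = qpcr.ddct_from_summary(4.0, 0.1, 5.0, 0.1)
        assert up.log2_fc > 0 and up.fold_change > 1
        assert down.log2_fc < 0 and down.fold_change < -1

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            qpcr.ddct_fold_change([5.0], [4.0, 4.1])


# ---------------------------------------------------------------------------
# tests and multiplicity
# ---------------------------------------------------------------------------

class TestEnrichment:
    def test_known_enrichments(self):
        """Enrichments (1.0, 1.2, 0.8, 1.0): mean 1, SE 0.0816, t ~ 12.25."""
        ip = np.array([0.0, 0.0, 0.0, 0.0])
        inp = np.array([1.0, 1.2, 0.8, 1.0])
        res = qpcr.enrichment_vs_input(ip, inp)
        assert res["log2_enrichment"] == pytest.approx(1.0)
        assert res["se"] == pytest.approx(0.0816, abs=5e-4)
        assert res["t"] == pytest.approx(1.0 / 0.08164965, rel=1e-5)
        assert res["df"] == 3

    def test_all_zero_convention(self):
        res = qpcr.enrichment_vs_input([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_sign_flip_symmetry(self):
        a = qpcr.enrichment_vs_input([0, 0, 0, 0], [1.0, 1.2, 0.8, 1.0])
        b = qpcr.enrichment_vs_input([1.0, 1.2, 0.8, 1.0], [0, 0, 0, 0])
        assert b["t"] == pytest.approx(-a["t"])
        assert b["p"] == pytest.approx(a["p"])


class TestGroupTest:
    def test_identical_constant_groups(self):
        t, df, p = qpcr.group_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert t == 0.0 and p == 1.0

    def test_matches_scipy_welch(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 2, 8)
        t, df, p = qpcr.group_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_large_separation(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(0, 1, 6) + 10 * np.std(a)
        _, _, p = qpcr.group_test(a, b)
        assert p < 1e-6


class TestHolmSidak:
    def test_single_p_unchanged(self):
        adj, rej = qpcr.holm_sidak([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_closed_form_two_values(self):
        adj, _ = qpcr.holm_sidak([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2, rel=1e-9)
        assert adj[1] == pytest.approx(0.04, rel=1e-9)

    def test_all_zero(self):
        adj, rej = qpcr.holm_sidak([0.0, 0.0, 0.0])
        assert (adj == 0).all() and rej.all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            qpcr.holm_sidak([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=8)
    )
    def test_step_down_formula_and_monotonicity(self, ps):
        """Adjusted values match max_{j<=i} 1-(1-p_(j))^(m-j+1), sorted-monotone."""
        adj, _ = qpcr.holm_sidak(ps)
        m = len(ps)
        order = np.argsort(ps)
        expect = np.empty(m)
        running = 0.0
        for i, j in enumerate(order):
            running = max(running, 1 - (1 - ps[j]) ** (m - i))
            expect[j] = min(1.0, running)
        np.testing.assert_allclose(adj, expect, atol=1e-9)


# ---------------------------------------------------------------------------
# estimator end to end
# ---------------------------------------------------------------------------

class TestReferenceGeneSelector:
    def test_recovers_designed_pair_and_effect(self):
        panel = default_panel()
        cands = [g.name for g in panel.genes if g.role == "reference"]
        table, truth = simulate_ct_table(panel, n_per_group=5, seed=42)
        sel = qpcr.ReferenceGeneSelector(candidate_genes=cands).fit(table)
        assert set(sel.selected_pair_) == set(truth.designed_pair)
        # the selected pair's own fold change is near 1 (Table-1-style check)
        assert abs(sel.pair_fold_change_) < 1.2
        dct = sel.transform(table)
        sub = dct[dct["gene"] == "Arc"]
        fc = qpcr.ddct_fold_change(
            sub.loc[sub["group"] == "sleep", "dCT"],
            sub.loc[sub["group"] == "SD", "dCT"],
        )
        assert fc.log2_fc == pytest.approx(1.26, abs=0.3)

    def test_ranking_invariant_to_gene_shift(self):
        panel = default_panel()
        cands = [g.name for g in panel.genes if g.role == "reference"]
        table, _ = simulate_ct_table(panel, n_per_group=4, seed=3)
        sel1 = qpcr.ReferenceGeneSelector(candidate_genes=cands).fit(table)
        shifted = table.copy()
        shifted.loc[shifted["gene"] == cands[0], "CT"] += 3.0
        sel2 = qpcr.ReferenceGeneSelector(candidate_genes=cands).fit(shifted)
        pd.testing.assert_series_equal(
            sel1.stability_["aggregated_rank"], sel2.stability_["aggregated_rank"]
        )

    def test_sklearn_params_roundtrip(self):
        sel = qpcr.ReferenceGeneSelector(candidate_genes=["a", "b", "c"], top_k=3)
        params = sel.get_params()
        assert params["top_k"] == 3
        sel.set_params(top_k=5)
        assert sel.top_k == 5
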