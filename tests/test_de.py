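"""Normalization, per-timepoint DE, interaction ANOVA and BH correction."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import nashtx as nx
from tests.conftest import log2_expr, make_design


def bh_bruteforce(p):
    """Exhaustive threshold scan: q_i = min over thresholds t >= p_i of
    the BH-adjusted value m * t / rank(t)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        cands = []
        for t in p:
            if t >= p[i]:
                rank = (p <= t).sum()
                cands.append(min(1.0, m * t / rank))
        q[i] = min(cands)
    return q


class TestQuantileNormalize:
    def test_hand_example(self):
        cm = nx.CountMatrix(np.array([[1, 4], [2, 5], [3, 6]]),
                            ["a", "b", "c"], ["s1", "s2"])
        out = nx.quantile_normalize(cm)
        np.testing.assert_allclose(out.values,
                                   [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_identical_columns_are_identity(self):
        vals = np.array([[5, 5], [1, 1], [9, 9]])
        cm = nx.CountMatrix(vals, ["a", "b", "c"], ["s1", "s2"])
        np.testing.assert_allclose(nx.quantile_normalize(cm).values, vals)

    def test_ties_get_mean_of_reference_block(self):
        # column 1 has a tie at rank positions 1 and 2
        cm = nx.CountMatrix(np.array([[1, 10], [1, 20], [4, 30]]),
                            ["a", "b", "c"], ["s1", "s2"])
        out = nx.quantile_normalize(cm)
        ref = np.sort(cm.values, axis=0).mean(axis=1)  # (5.5, 10.5, 17.0)
        np.testing.assert_allclose(out.values[:, 0],
                                   [(ref[0] + ref[1]) / 2] * 2 + [ref[2]])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 12), st.integers(2, 5))
    def test_sorted_columns_pairwise_equal(self, seed, n, m):
        # tie-free columns: with ties the tie-averaged sorted vector may
        # deviate from the reference (by construction of the tie rule)
        rng = np.random.default_rng(seed)
        vals = np.empty((n, m))
        for j in range(m):
            vals[:, j] = rng.choice(50 * n, size=n, replace=False)
        cm = nx.CountMatrix(vals.astype(int), [f"g{i}" for i in range(n)],
                            [f"s{j}" for j in range(m)])
        out = np.sort(nx.quantile_normalize(cm).values, axis=0)
        for j in range(1, m):
            np.testing.assert_allclose(out[:, j], out[:, 0])

    def test_single_sample_rejected(self):
        cm = nx.CountMatrix(np.array([[1], [2]]), ["a", "b"], ["s1"])
        with pytest.raises(ValueError):
            nx.quantile_normalize(cm)


class TestLog2Transform:
    def test_examples_and_round_trip(self):
        expr = nx.ExprMatrix(np.array([[0.0, 3.0]]), ["g"], ["s1", "s2"])
        out = nx.log2_transform(expr, pseudocount=1.0)
        np.testing.assert_allclose(out.values, [[0.0, 2.0]])
        assert out.scale == "log2"
        np.testing.assert_allclose(2.0**out.values - 1.0, expr.values, atol=1e-12)

    def test_nonpositive_pseudocount_rejected(self):
        expr = nx.ExprMatrix(np.array([[1.0]]), ["g"], ["s"])
        with pytest.raises(ValueError):
            nx.log2_transform(expr, pseudocount=0.0)


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.05], [0.05]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_examples(self, p, expected):
        np.testing.assert_allclose(nx.bh_fdr(p), expected)

    def test_nan_passthrough_and_exclusion(self):
        q = nx.bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # m=2 after exclusion
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nx.bh_fdr([0.5, 1.5])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_matches_bruteforce_threshold_scan(self, p):
        np.testing.assert_allclose(nx.bh_fdr(p), bh_bruteforce(p), atol=1e-9)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = nx.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDePerTimepoint:
    def test_welch_oracle_example(self):
        """LFD (1.0,1.1,0.9,1.0) vs WD (3.0,3.1,2.9,3.0): log2fc 2, FC 4,
        Welch t = 34.64 (verified against scipy), called up."""
        design = make_design(n_per_cell=4)
        vals = np.zeros((1, 16))
        lfd1 = [design.sample_ids.index(s) for s in design.samples_for("LFD", 1)]
        wd1 = [design.sample_ids.index(s) for s in design.samples_for("WD", 1)]
        vals[0, lfd1] = [1.0, 1.1, 0.9, 1.0]
        vals[0, wd1] = [3.0, 3.1, 2.9, 3.0]
        tab = nx.de_per_timepoint(log2_expr(vals, design), design, 1)
        row = tab.iloc[0]
        assert row["log2fc"] == pytest.approx(2.0)
        assert row["fold_change"] == pytest.approx(4.0)
        ref = stats.ttest_ind([3.0, 3.1, 2.9, 3.0], [1.0, 1.1, 0.9, 1.0],
                              equal_var=False)
        assert row["p_value"] == pytest.approx(ref.pvalue, rel=1e-9)
        assert row["call"] == "up"

    def test_thresholds_inclusive_and_fc_gate_mandatory(self):
        """A 2.0-fold gene at exactly q=0.1 is up; a 1.9-fold gene is ns no
        matter how significant."""
        rng = np.random.default_rng(5)
        design = make_design(n_per_cell=10)
        n = 40
        vals = rng.normal(5.0, 0.05, (n, len(design.sample_ids)))
        wd1 = [design.sample_ids.index(s) for s in design.samples_for("WD", 1)]
        lfd1 = [design.sample_ids.index(s) for s in design.samples_for("LFD", 1)]
        jitter = np.linspace(-0.05, 0.05, 10)
        # identical within-group pattern -> group means differ by exactly 1.0
        vals[0, lfd1] = 5.0 + jitter
        vals[0, wd1] = 6.0 + jitter
        vals[1, lfd1] = 5.0 + jitter
        vals[1, wd1] = 5.0 + np.log2(1.9) + jitter  # strong but sub-threshold
        tab = nx.de_per_timepoint(log2_expr(vals, design), design, 1)
        assert tab.iloc[0]["fold_change"] == pytest.approx(2.0, abs=1e-12)
        assert tab.iloc[0]["call"] == "up"
        assert tab.iloc[1]["q_value"] < 0.01
        assert tab.iloc[1]["call"] == "ns"

    def test_zero_variance_reported_nan_ns(self, caplog):
        design = make_design(n_per_cell=3)
        vals = np.ones((2, len(design.sample_ids)))
        vals[1] = np.random.default_rng(0).normal(size=len(design.sample_ids))
        tab = nx.de_per_timepoint(log2_expr(vals, design), design, 1)
        assert np.isnan(tab.iloc[0]["p_value"])
        assert tab.iloc[0]["call"] == "ns"
        assert np.isfinite(tab.iloc[1]["p_value"])

    def test_missing_group_rejected(self):
        design = make_design(n_per_cell=3)
        vals = np.zeros((1, len(design.sample_ids)))
        lfd_only = nx.DesignTable(
            design.table[design.table["diet"] == "LFD"].reset_index(drop=True)
        )
        expr = nx.ExprMatrix(vals[:, :len(lfd_only.sample_ids)], ["g0000"],
                             lfd_only.sample_ids, scale="log2")
        with pytest.raises(ValueError):
            nx.de_per_timepoint(expr, lfd_only, 1)


class TestInteraction:
    def test_hand_anova_decomposition(self):
        """Cells LFD1=(1,2) WD1=(1,2) LFD40=(1,2) WD40=(5,6):
        SS_int=8, MS_within=0.5, F=16 on (1,4), p~0.016."""
        design = make_design(n_per_cell=2)
        vals = np.zeros((1, 8))
        for cell, data in [(("LFD", 1), [1, 2]), (("WD", 1), [1, 2]),
                           (("LFD", 40), [1, 2]), (("WD", 40), [5, 6])]:
            idx = [design.sample_ids.index(s) for s in design.samples_for(*cell)]
            vals[0, idx] = data
        tab = nx.interaction_test(log2_expr(vals, design), design)
        assert tab.iloc[0]["F_stat"] == pytest.approx(16.0, abs=1e-9)
        assert tab.iloc[0]["p_value"] == pytest.approx(stats.f.sf(16, 1, 4), abs=1e-9)
        assert tab.iloc[0]["log2fc_40wk"] == pytest.approx(4.0)

    def test_agrees_with_statsmodels_anova(self):
        """Independent oracle: statsmodels OLS ANOVA interaction F/p on an
        unbalanced design."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(10)
        rows, vals = [], []
        for diet, time, n in [("LFD", 1, 4), ("WD", 1, 8), ("LFD", 40, 4), ("WD", 40, 8)]:
            for i in range(n):
                rows.append({"sample_id": f"{diet}{time}_{i}", "diet": diet,
                             "time": time, "sex": "F" if i % 2 else "M"})
        design = nx.DesignTable(pd.DataFrame(rows))
        x = rng.normal(0, 1, (3, len(rows)))
        tab = nx.interaction_test(log2_expr(x, design), design)
        df = pd.DataFrame(rows)
        for g in range(3):
            df["y"] = x[g]
            fit = smf.ols("y ~ C(diet) * C(time)", data=df).fit()
            aov = sm.stats.anova_lm(fit, typ=2)
            f_ref = aov.loc["C(diet):C(time)", "F"]
            p_ref = aov.loc["C(diet):C(time)", "PR(>F)"]
            assert tab.iloc[g]["F_stat"] == pytest.approx(f_ref, rel=1e-8)
            assert tab.iloc[g]["p_value"] == pytest.approx(p_ref, rel=1e-8)

    def test_f_equals_squared_contrast_t_balanced(self):
        """On a balanced 2x2, F equals the squared t of the difference of
        diet contrasts (algebraic identity)."""
        rng = np.random.default_rng(3)
        design = make_design(n_per_cell=5)
        x = rng.normal(0, 1, (10, 20))
        tab = nx.interaction_test(log2_expr(x, design), design)
        cols = {s: i for i, s in enumerate(design.sample_ids)}
        cells = {(d, t): [cols[s] for s in design.samples_for(d, t)]
                 for d in ("LFD", "WD") for t in (1, 40)}
        for g in range(10):
            means = {k: x[g, v].mean() for k, v in cells.items()}
            L = (means[("WD", 40)] - means[("LFD", 40)]
                 - means[("WD", 1)] + means[("LFD", 1)])
            ss_w = sum(((x[g, v] - means[k]) ** 2).sum() for k, v in cells.items())
            t_stat = L / np.sqrt(ss_w / 16 * (4 / 5))
            assert tab.iloc[g]["F_stat"] == pytest.approx(t_stat**2, rel=1e-9)

    def test_null_pvalues_uniform(self):
        """Main effects without interaction leave the interaction p-values
        uniform (KS test over 2000 simulated genes)."""
        rng = np.random.default_rng(17)
        design = make_design(n_per_cell=6)
        n = 2000
        x = rng.normal(0, 0.5, (n, 24))
        cols = {s: i for i, s in enumerate(design.sample_ids)}
        wd = [cols[s] for s in design.samples_for(diet="WD")]
        late = [cols[s] for s in design.samples_for(time=40)]
        x[:, wd] += 1.0    # diet main effect on every gene
        x[:, late] += 0.5  # time main effect
        tab = nx.interaction_test(log2_expr(x, design), design)
        ks = stats.kstest(tab["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_permutation_null_matches_f_distribution(self):
        """Permuting diet labels within each time stratum reproduces the
        null F distribution on a small instance."""
        rng = np.random.default_rng(23)
        design = make_design(n_per_cell=4)
        x = rng.normal(0, 1, (1, 16))
        obs = nx.interaction_test(log2_expr(x, design), design).iloc[0]["F_stat"]
        perm_f = []
        base = design.table
        for _ in range(300):
            t = base.copy()
            for time in (1, 40):
                idx = t.index[t["time"] == time].to_numpy()
                t.loc[idx, "diet"] = t.loc[rng.permutation(idx), "diet"].values
            perm = nx.DesignTable(t)
            perm_f.append(
                nx.interaction_test(log2_expr(x, design), perm).iloc[0]["F_stat"]
            )
        emp_p = np.mean(np.asarray(perm_f) >= obs)
        theo_p = stats.f.sf(obs, 1, 12)
        assert emp_p == pytest.approx(theo_p, abs=0.12)

    def test_empty_cell_rejected(self, bulk_sim):
        _, counts, design, _ = bulk_sim
        expr = nx.log2_transform(nx.quantile_normalize(counts))
        only_1wk = nx.DesignTable(
            design.table[design.table["time"] == 1].reset_index(drop=True)
        )
        with pytest.raises(ValueError):
            nx.interaction_test(expr, only_1wk)


class TestOverlapAndSelection:
    @staticmethod
    def _table(universe, up=(), down=()):
        call = pd.Series("ns", index=pd.Index(universe, name="gene_id"))
        call[list(up)] = "up"
        call[list(down)] = "down"
        return pd.DataFrame({"call": call})

    def test_overlap_example(self):
        uni = ["A", "B", "C", "D"]
        s = nx.overlap_sets(self._table(uni, up=["A"], down=["B"]),
                            self._table(uni, up=["C"], down=["B"]))
        assert (s.n_common, s.common_genes) == (1, ["B"])
        assert s.n_total_1wk == s.n_up_1wk + s.n_down_1wk == 2

    def test_no_calls(self):
        uni = ["A", "B"]
        s = nx.overlap_sets(self._table(uni), self._table(uni))
        assert (s.n_total_1wk, s.n_total_40wk, s.n_common) == (0, 0, 0)

    def test_disjoint_universes_rejected(self):
        with pytest.raises(ValueError):
            nx.overlap_sets(self._table(["A"]), self._table(["B"]))

    def test_progressive_gene_gates(self):
        tab = pd.DataFrame(
            {
                "q_value": [0.05, 0.05, 0.05, 0.5],
                "log2fc_1wk": [0.5, -0.2, 0.5, 0.5],
                "log2fc_40wk": [1.6, 1.6, 0.58, 1.6],
            },
            index=pd.Index(["keep", "neg1wk", "weak40wk", "notsig"], name="gene_id"),
        )
        assert nx.select_progressive_genes(tab) == ["keep"]

    def test_progressive_gates_strict(self):
        tab = pd.DataFrame(
            {"q_value": [0.1], "log2fc_1wk": [0.0], "log2fc_40wk": [1.0]},
            index=pd.Index(["edge"], name="gene_id"),
        )
        # fold-change gates are strict (> 0 and > 2-fold), FDR inclusive
        assert nx.select_progressive_genes(tab) == []


class TestGateOrderIndependence:
    def test_filter_then_bh_equals_bh_then_filter(self, bulk_sim):
        """On one tested universe, applying the fold-change gate before or
        after BH yields the same call set (q depends only on p)."""
        _, counts, design, _ = bulk_sim
        expr = nx.log2_transform(nx.quantile_normalize(counts))
        tab = nx.de_per_timepoint(expr, design, 40)
        q = nx.bh_fdr(tab["p_value"])
        calls_manual = (
            ((tab["fold_change"] >= 2.0) | (tab["fold_change"] <= 0.5))
            & (pd.Series(q, index=tab.index) <= 0.1)
        )
        assert set(tab.index[tab["call"] != "ns"]) == set(tab.index[calls_manual])
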