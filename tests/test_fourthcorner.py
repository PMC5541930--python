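import numpy as np
import pandas as pd
import pytest

from patchtraits import (
    StudyTables,
    ValidationError,
    axes_association_test,
    combined_test,
    correspondence_weights,
    fourth_corner_matrix,
    permutation_test,
    rlq,
    weighted_standardize,
)

from .conftest import random_tables


def inflated_table_corr(tables: StudyTables, trait: str, metric: str) -> float:
    """Independent oracle: build the abundance-inflated table cell by cell
    and compute the weighted Pearson correlation between the metric value of
    the plot and the trait value of the species, weighted by P[i, s]."""
    P, _, _ = correspondence_weights(tables.L)
    xs, ys, ws = [], [], []
    for i, plot in enumerate(tables.L.index):
        for s, sp in enumerate(tables.L.columns):
            w = P.iloc[i, s]
            if w == 0:
                continue
            xs.append(tables.R.loc[plot, metric])
            ys.append(tables.Q.loc[sp, trait])
            ws.append(w)
    x, y, w = map(np.asarray, (xs, ys, ws))
    mx, my = (w * x).sum(), (w * y).sum()
    cov = (w * (x - mx) * (y - my)).sum()
    return cov / np.sqrt((w * (x - mx) ** 2).sum() * (w * (y - my) ** 2).sum())


class TestFourthCornerMatrix:
    def test_matches_inflated_table_oracle_cellwise(self, small_tables):
        X = fourth_corner_matrix(small_tables)
        for trait in small_tables.Q.columns:
            for metric in small_tables.R.columns:
                want = inflated_table_corr(small_tables, trait, metric)
                assert X.loc[trait, metric] == pytest.approx(want, abs=1e-12)

    def test_micro_table_by_hand(self):
        # 2 plots x 2 species, 1 metric, 1 trait; exhaustive summation
        L = pd.DataFrame([[3, 1], [1, 3]], index=["p1", "p2"], columns=["s1", "s2"])
        R = pd.DataFrame({"m": [0.0, 1.0]}, index=["p1", "p2"])
        Q = pd.DataFrame({"t": [0.0, 1.0]}, index=["s1", "s2"])
        t = StudyTables.from_frames(R, L, Q)
        X = fourth_corner_matrix(t)
        assert X.loc["t", "m"] == pytest.approx(inflated_table_corr(t, "t", "m"), abs=1e-14)
        # symmetric design: positive association, |x| < 1
        assert 0 < X.loc["t", "m"] < 1

    def test_constant_trait_is_rejected_by_precheck(self, small_tables):
        from patchtraits import DegenerateInputError

        t = small_tables
        Q2 = t.Q.copy()
        Q2.iloc[:, 0] = 1.0
        t2 = StudyTables(R=t.R, L=t.L, Q=Q2, covariates=t.covariates)
        with pytest.raises(DegenerateInputError, match="t0"):
            fourth_corner_matrix(t2)

    def test_statistic_scale_invariant_in_trait_amplitude(self, small_tables):
        # the normed statistic sees only the shape of a trait's variation,
        # not its amplitude: shrinking the deviations 10^9-fold changes nothing
        t = small_tables
        Q2 = t.Q.copy()
        Q2.iloc[:, 0] = 1.0 + 1e-9 * (Q2.iloc[:, 0] - Q2.iloc[:, 0].mean())
        t2 = StudyTables(R=t.R, L=t.L, Q=Q2, covariates=t.covariates)
        X1 = fourth_corner_matrix(t)
        X2 = fourth_corner_matrix(t2)
        assert np.allclose(X1.iloc[0], X2.iloc[0], atol=1e-6)

    def test_entries_bounded_by_one(self, small_tables):
        X = fourth_corner_matrix(small_tables).to_numpy()
        assert (np.abs(X) <= 1 + 1e-12).all()

    def test_sum_of_squares_equals_rlq_total_inertia(self):
        for seed in (0, 1, 2, 3):
            t = random_tables(seed=seed)
            X = fourth_corner_matrix(t).to_numpy()
            res = rlq(t)
            assert (X**2).sum() == pytest.approx(res.eigenvalues.sum(), abs=1e-10)


class TestPermutationTest:
    def test_identity_permutation_gives_p_one(self, small_tables):
        n = small_tables.R.shape[0]
        res = permutation_test(small_tables, model=2, permutations=[np.arange(n)])
        assert (res.p_cells.to_numpy() == 1.0).all()
        assert res.global_test.p == 1.0

    def test_literal_permute_l_matches_fast_permute_r(self, small_tables):
        """Permuting rows of L (weights travelling with the rows) must equal
        the implementation's permute-rows-of-R shortcut."""
        t = small_tables
        rng = np.random.default_rng(5)
        sigma = rng.permutation(t.L.shape[0])
        # literal: permute L rows (and covariate pairing), recompute everything
        L_perm = pd.DataFrame(t.L.to_numpy()[sigma], index=t.L.index, columns=t.L.columns)
        literal = fourth_corner_matrix(StudyTables(R=t.R, L=L_perm, Q=t.Q))
        # shortcut: permute R rows by the inverse permutation
        inv = np.argsort(sigma)
        P, r, c = correspondence_weights(t.L)
        Rt = weighted_standardize(
            pd.DataFrame(t.R.to_numpy()[inv], index=t.R.index, columns=t.R.columns), r
        )
        Qt = weighted_standardize(t.Q, c)
        shortcut = Rt.to_numpy().T @ P.to_numpy() @ Qt.to_numpy()
        assert np.allclose(literal.to_numpy(), shortcut.T, atol=1e-12)

    def test_model4_breaks_lq_but_preserves_lr(self, small_tables):
        n_sp = small_tables.Q.shape[0]
        res = permutation_test(small_tables, model=4, permutations=[np.arange(n_sp)])
        assert res.global_test.p == 1.0

    def test_invalid_model_rejected(self, small_tables):
        with pytest.raises(ValidationError):
            permutation_test(small_tables, model=3)

    def test_seed_reproducibility(self, small_tables):
        a = permutation_test(small_tables, 2, n_perm=99, seed=7)
        b = permutation_test(small_tables, 2, n_perm=99, seed=7)
        assert a.p_cells.equals(b.p_cells)
        assert a.global_test.p == b.global_test.p

    def test_exchangeability_joint_plot_permutation_changes_nothing(self, small_tables):
        t = small_tables
        rng = np.random.default_rng(17)
        sigma = rng.permutation(t.R.shape[0])
        R2 = pd.DataFrame(t.R.to_numpy()[sigma], index=t.R.index, columns=t.R.columns)
        L2 = pd.DataFrame(t.L.to_numpy()[sigma], index=t.L.index, columns=t.L.columns)
        t2 = StudyTables(R=R2, L=L2, Q=t.Q, covariates=t.covariates)
        X1 = fourth_corner_matrix(t)
        X2 = fourth_corner_matrix(t2)
        assert np.allclose(X1.to_numpy(), X2.to_numpy(), atol=1e-12)
        # seeded p-values identical as well: permuting species (model 4) is
        # blind to the joint plot relabeling
        p1 = permutation_test(t, 4, n_perm=49, seed=3).p_cells
        p2 = permutation_test(t2, 4, n_perm=49, seed=3).p_cells
        assert p1.equals(p2)


class TestCombinedTest:
    def test_max_p_rule_and_flags(self, small_tables):
        res = combined_test(small_tables, n_perm=99, seed=1)
        pc = res.p_combined.to_numpy()
        assert np.allclose(pc, np.maximum(res.p_model2.to_numpy(), res.p_model4.to_numpy()))
        assert ((pc > 0) & (pc <= 1)).all()
        assert (res.significant_sqrt05.to_numpy() == (pc < np.sqrt(0.05))).all()
        assert (res.significant_05.to_numpy() == (pc < 0.05)).all()
        # a cell passing one model only is never flagged
        one_sided = (res.p_model2.to_numpy() < 0.05) & (res.p_model4.to_numpy() >= 0.05)
        assert not (one_sided & res.significant_05.to_numpy()).any()

    def test_summary_table_layout(self, small_tables):
        res = combined_test(small_tables, n_perm=49, seed=0)
        tab = res.summary_table()
        assert list(tab.columns) == [
            "trait", "metric", "statistic", "p_model2", "p_model4",
            "p_combined", "sig_sqrt05", "sig_05",
        ]
        assert len(tab) == small_tables.Q.shape[1] * small_tables.R.shape[1]

    def test_fdr_flagging_is_never_more_liberal(self, small_tables):
        raw = combined_test(small_tables, n_perm=99, seed=2)
        adj = combined_test(small_tables, n_perm=99, seed=2, fdr=True)
        assert (adj.significant_05.to_numpy() <= raw.significant_05.to_numpy()).all()


class TestAxesAssociation:
    def test_axis_score_correlates_perfectly_with_itself(self, small_tables):
        res = rlq(small_tables)
        t = small_tables
        R2 = t.R.copy()
        R2["self"] = res.plot_scores["axis1"]
        t2 = StudyTables(R=R2, L=t.L, Q=t.Q, covariates=t.covariates)
        res2 = rlq(t2)
        out = axes_association_test(t2, res2, n_perm=49, seed=0)
        # correlation of the injected copy with the axis it now dominates
        assert abs(out.loc["self", "corr_axis1"]) > 0.95

    def test_d2_is_squared_correlation(self, small_tables):
        res = rlq(small_tables)
        out = axes_association_test(small_tables, res, n_perm=49, seed=1)
        assert np.allclose(out["d2_axis1"], out["corr_axis1"] ** 2)

    def test_null_variable_p_values_are_spread_out(self):
        # a variable independent of everything should give unremarkable p
        rng = np.random.default_rng(0)
        ps = []
        for seed in range(12):
            t = random_tables(seed=100 + seed, n_plots=10)
            res = rlq(t)
            R2 = t.R.copy()
            R2["noise"] = rng.normal(size=10)
            t2 = StudyTables(R=R2, L=t.L, Q=t.Q, covariates=t.covariates)
            res2 = rlq(t2)
            out = axes_association_test(t2, res2, n_perm=99, seed=seed)
            ps.append(out.loc["noise", "p_axis1"])
        ps = np.array(ps)
        assert ps.min() < 0.9 and ps.max() > 0.1  # not degenerate
        assert 0.15 < ps.mean() < 0.85  # roughly uniform on average
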