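"""Signed-hybrid network, TOM, dynamic cut, merging, scores, edge export."""

import numpy as np
import pandas as pd
import pytest

from sarcomics.modules import (
    UNGROUPED,
    NetworkConfig,
    detect_modules,
    export_edge_list,
    merge_close_modules,
    module_score,
    pick_soft_threshold,
    signed_hybrid_adjacency,
    tertile_stratify,
    tom_dissimilarity,
)


def _planted_cohort(seed=0, blocks=5, block_size=50, noise=500, n=100, r=0.7):
    rng = np.random.default_rng(seed)
    rows, membership = [], []
    lam = np.sqrt(r / (1 - r))
    for b in range(blocks):
        factor = rng.standard_normal(n)
        rows.append(lam * factor[None, :] + rng.standard_normal((block_size, n)))
        membership += [f"B{b}"] * block_size
    rows.append(rng.standard_normal((noise, n)))
    membership += [""] * noise
    X = np.vstack(rows)
    df = pd.DataFrame(
        X,
        index=[f"p{i}" for i in range(X.shape[0])],
        columns=[f"s{j}" for j in range(n)],
    )
    return df, pd.Series(membership, index=df.index)


class TestAdjacency:
    def test_negative_correlations_zeroed(self):
        cor = np.array([[1.0, -0.3], [-0.3, 1.0]])
        a = signed_hybrid_adjacency(cor, 5)
        assert a[0, 1] == 0.0

    def test_power_example(self):
        cor = np.array([[1.0, 0.5], [0.5, 1.0]])
        a = signed_hybrid_adjacency(cor, 5)
        assert a[0, 1] == pytest.approx(0.03125)

    def test_matches_elementwise_brute_force(self, rng):
        X = rng.normal(size=(10, 40))
        cor = np.corrcoef(X)
        a = signed_hybrid_adjacency(cor, 5)
        for i in range(10):
            for j in range(10):
                expected = 1.0 if i == j else (
                    cor[i, j] ** 5 if cor[i, j] > 0 else 0.0
                )
                assert a[i, j] == pytest.approx(expected, abs=1e-12)


class TestTom:
    def test_hand_evaluated_three_node(self):
        a = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        diss = tom_dissimilarity(a)
        # TOM12 = (0.2*0.4 + 0.5) / (min(0.7, 0.9) + 1 - 0.5)
        assert 1 - diss[0, 1] == pytest.approx(0.58 / 1.2)

    def test_isolated_nodes(self):
        a = np.eye(4)
        diss = tom_dissimilarity(a)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(diss[off], 1.0)

    def test_clique(self):
        a = np.ones((5, 5))
        diss = tom_dissimilarity(a)
        assert np.allclose(diss, 0.0)

    def test_brute_force_equivalence(self, rng):
        X = rng.normal(size=(15, 30))
        a = signed_hybrid_adjacency(np.corrcoef(X), 3)
        diss = tom_dissimilarity(a)
        p = a.shape[0]
        for i in range(p):
            for j in range(p):
                if i == j:
                    assert diss[i, j] == 0.0
                    continue
                l_ij = sum(
                    a[i, u] * a[u, j] for u in range(p) if u not in (i, j)
                )
                k_i = sum(a[i, u] for u in range(p) if u != i)
                k_j = sum(a[j, u] for u in range(p) if u != j)
                tom = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
                assert 1 - diss[i, j] == pytest.approx(tom, abs=1e-12)

    def test_entries_in_unit_interval_and_symmetric(self, rng):
        a = signed_hybrid_adjacency(np.corrcoef(rng.normal(size=(30, 50))), 5)
        diss = tom_dissimilarity(a)
        assert diss.min() >= -1e-12 and diss.max() <= 1 + 1e-12
        assert np.allclose(diss, diss.T)

    def test_asymmetric_input_rejected(self):
        a = np.array([[1.0, 0.4], [0.5, 1.0]])
        with pytest.raises(ValueError):
            tom_dissimilarity(a)


def _hub_cohort(seed=0, p=300, n=100, nf=4):
    """Factor model with power-law loadings: a few hub proteins produce an
    approximately scale-free connectivity distribution."""
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((nf, n))
    u = rng.uniform(0.05, 1, size=p)
    lam = np.clip(2.0 * u**-0.45 - 1.5, 0, 6)
    which = rng.integers(0, nf, size=p)
    X = lam[:, None] * F[which] + rng.standard_normal((p, n))
    return pd.DataFrame(X, index=[f"p{i}" for i in range(p)])


class TestPickSoftThreshold:
    def test_hub_cohort_suggestion_tracks_best_fit(self):
        for seed in range(3):
            table, suggested = pick_soft_threshold(
                _hub_cohort(seed), beta_grid=range(1, 13)
            )
            assert suggested is not None
            assert table.loc[suggested, "r2"] >= 0.8
            assert abs(suggested - int(table["r2"].idxmax())) <= 3

    def test_uncorrelated_noise_flagged_unreliable(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 40)))
        table, suggested = pick_soft_threshold(df, beta_grid=range(1, 7))
        assert suggested is None


class TestDetectModules:
    def test_planted_blocks_recovered(self):
        df, truth = _planted_cohort(seed=1)
        cor = np.corrcoef(df.to_numpy())
        diss = tom_dissimilarity(signed_hybrid_adjacency(cor, 5))
        assignment = detect_modules(diss, NetworkConfig(), df.index, matrix=df)
        recovered = 0
        for b in sorted(set(truth) - {""}):
            planted = set(truth.index[truth == b])
            best = max(
                (
                    len(planted & set(assignment.members(m)))
                    / len(planted | set(assignment.members(m)))
                    for m in set(assignment.membership) - {UNGROUPED}
                ),
                default=0.0,
            )
            recovered += best >= 0.8
        assert recovered >= 4
        noise_ids = truth.index[truth == ""]
        assert (assignment.membership[noise_ids] == UNGROUPED).mean() > 0.5

    def test_min_size_respected(self):
        df, _ = _planted_cohort(seed=2, blocks=2, block_size=40, noise=100)
        cor = np.corrcoef(df.to_numpy())
        diss = tom_dissimilarity(signed_hybrid_adjacency(cor, 5))
        assignment = detect_modules(diss, NetworkConfig(), df.index, matrix=df)
        assert (assignment.module_sizes >= 30).all()

    def test_tiny_input_all_ungrouped(self, rng):
        diss = 1 - np.eye(5)
        with pytest.warns(UserWarning):
            assignment = detect_modules(diss, NetworkConfig())
        assert (assignment.membership == UNGROUPED).all()

    def test_correlated_summary_profiles_merged(self):
        rng = np.random.default_rng(3)
        n = 80
        f1 = rng.standard_normal(n)
        f2 = 0.95 * f1 + np.sqrt(1 - 0.95**2) * rng.standard_normal(n)
        lam = 3.0
        X = np.vstack(
            [
                lam * f1[None, :] + rng.standard_normal((40, n)),
                lam * f2[None, :] + rng.standard_normal((40, n)),
            ]
        )
        df = pd.DataFrame(X, index=[f"p{i}" for i in range(80)])
        membership = pd.Series(
            ["A"] * 40 + ["B"] * 40, index=df.index
        )
        merged = merge_close_modules(df, membership, merge_cut_height=0.25)
        assert merged.nunique() == 1

    def test_merge_is_idempotent(self):
        df, truth = _planted_cohort(seed=4, blocks=3, block_size=40, noise=50)
        membership = truth.replace("", UNGROUPED)
        once = merge_close_modules(df, membership)
        twice = merge_close_modules(df, once)
        pd.testing.assert_series_equal(once, twice)

    def test_reordering_invariance_up_to_relabelling(self):
        from sklearn.metrics import adjusted_rand_score

        df, _ = _planted_cohort(seed=5, blocks=3, block_size=35, noise=80)
        cor = np.corrcoef(df.to_numpy())
        diss = tom_dissimilarity(signed_hybrid_adjacency(cor, 5))
        a1 = detect_modules(diss, NetworkConfig(), df.index, matrix=df)
        perm = np.random.default_rng(0).permutation(df.shape[0])
        df_p = df.iloc[perm]
        diss_p = diss[np.ix_(perm, perm)]
        a2 = detect_modules(diss_p, NetworkConfig(), df_p.index, matrix=df_p)
        joint = pd.DataFrame(
            {"a": a1.membership, "b": a2.membership.reindex(a1.membership.index)}
        )
        assert adjusted_rand_score(joint["a"], joint["b"]) == pytest.approx(1.0)


class TestModuleScores:
    def test_single_protein_module_score_is_row(self, rng):
        df = pd.DataFrame(rng.normal(size=(3, 6)),
                          index=["a", "b", "c"])
        membership = pd.Series(["M1", "", ""], index=df.index)
        score = module_score(df, membership, "M1")
        np.testing.assert_allclose(score.to_numpy(), df.loc["a"].to_numpy())

    def test_score_is_member_median(self, rng):
        df = pd.DataFrame(rng.normal(size=(7, 10)))
        membership = pd.Series(["M1"] * 5 + [""] * 2, index=df.index)
        score = module_score(df, membership, "M1")
        np.testing.assert_allclose(
            score.to_numpy(), df.iloc[:5].median(axis=0).to_numpy()
        )

    def test_absent_module_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(3, 4)))
        membership = pd.Series([""] * 3, index=df.index)
        with pytest.raises(ValueError):
            module_score(df, membership, "M9")

    def test_nine_distinct_scores_split_three_ways(self):
        score = pd.Series(np.arange(9, dtype=float))
        strata = tertile_stratify(score)
        assert strata.value_counts().to_dict() == {
            "low": 3, "intermediate": 3, "high": 3,
        }
        assert (strata.iloc[:3] == "low").all()
        assert (strata.iloc[6:] == "high").all()

    @pytest.mark.parametrize("n", [7, 10, 11, 30, 100])
    def test_strata_sizes_differ_by_at_most_one(self, n, rng):
        score = pd.Series(rng.permutation(n).astype(float))
        counts = tertile_stratify(score).value_counts()
        assert counts.max() - counts.min() <= 1


class TestExportEdgeList:
    def test_threshold_one_empty(self, rng):
        S = np.abs(np.corrcoef(rng.normal(size=(4, 20))))
        edges = export_edge_list(S, list("abcd"), threshold=1.0)
        assert edges.empty

    def test_matches_brute_force_scan(self):
        S = np.array(
            [
                [1.0, 0.2, 0.01, 0.0],
                [0.2, 1.0, 0.3, 0.04],
                [0.01, 0.3, 1.0, 0.9],
                [0.0, 0.04, 0.9, 1.0],
            ]
        )
        edges = export_edge_list(S, list("abcd"), threshold=0.05)
        got = {tuple(r) for r in edges[["source", "target"]].to_numpy()}
        assert got == {("a", "b"), ("b", "c"), ("c", "d")}

    def test_module_annotation_attached(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        membership = pd.Series(["M1", UNGROUPED], index=["a", "b"])
        edges = export_edge_list(S, ["a", "b"], 0.05, membership)
        assert edges.loc[0, "source_module"] == "M1"
        assert edges.loc[0, "target_module"] == UNGROUPED
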