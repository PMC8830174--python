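"""Survey statistics: scaling, Ward clustering, PCA, Pearson scans."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import digestate as dg


def ward_oracle(x: np.ndarray):
    """Brute-force O(n^3) Ward agglomeration.

    Maintains explicit clusters and merges the pair with the smallest
    Ward distance sqrt(2 |A||B| / (|A|+|B|)) * ||cA - cB||, tie-broken by
    lowest member index.  Returns the merge sequence as frozensets of
    original row indices with merge heights.
    """
    clusters = [frozenset([i]) for i in range(len(x))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            ca = x[list(a)].mean(axis=0)
            cb = x[list(b)].mean(axis=0)
            d = np.sqrt(
                2.0 * len(a) * len(b) / (len(a) + len(b))
            ) * np.linalg.norm(ca - cb)
            key = (d, min(min(a), min(b)))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        merges.append((a | b, d))
    return merges


def linkage_merge_sets(z: np.ndarray, n: int):
    """Merge sequence of a SciPy linkage matrix as member-index sets."""
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (i, j, h, _) in enumerate(z):
        merged = members[int(i)] | members[int(j)]
        members[n + k] = merged
        out.append((merged, h))
    return out


class TestScalingAndMissingness:
    def test_scaled_columns_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(5, 3, size=(12, 4)), columns=list("abcd"))
        scaled = dg.scale_features(df)
        assert np.allclose(scaled.mean(), 0.0, atol=1e-9)
        assert np.allclose(scaled.std(ddof=1), 1.0, atol=1e-9)

    def test_drop_incomplete(self):
        df = pd.DataFrame({"full": [1.0, 2.0, 3.0], "holey": [1.0, np.nan, 3.0]})
        kept = dg.drop_incomplete(df)
        assert list(kept.columns) == ["full"]
        complete = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        assert dg.drop_incomplete(complete).equals(complete)

    def test_drop_incomplete_empty_result_errors(self):
        with pytest.raises(ValueError):
            dg.drop_incomplete(pd.DataFrame({"a": [1.0, np.nan]}))

    def test_injected_missingness_is_what_gets_dropped(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(8, 5)), columns=list("abcde"))
        df.loc[2, "b"] = np.nan
        df.loc[5, "d"] = np.nan
        assert list(dg.drop_incomplete(df).columns) == ["a", "c", "e"]


class TestWardClustering:
    def test_identical_rows_merge_at_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        z = dg.ward_cluster(df)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_collinear_points_first_merge_nearest(self):
        df = pd.DataFrame([[0.0], [1.0], [10.0]])
        z = dg.ward_cluster(df)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=(8, 5))
        z = dg.ward_cluster(pd.DataFrame(x))
        got = linkage_merge_sets(z, 8)
        want = ward_oracle(x)
        assert [m for m, _ in got] == [m for m, _ in want]
        assert np.allclose([h for _, h in got], [h for _, h in want], atol=1e-9)

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(7)
        z = dg.ward_cluster(pd.DataFrame(rng.normal(size=(10, 3))))
        assert np.all(np.diff(z[:, 2]) >= -1e-12)

    def test_rejects_missing_values(self):
        with pytest.raises(ValueError):
            dg.ward_cluster(pd.DataFrame([[1.0, np.nan], [2.0, 3.0]]))


class TestPca:
    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        df = dg.scale_features(pd.DataFrame(rng.normal(size=(10, 4))))
        res = dg.pca(df)
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_bivariate_closed_form(self):
        """For two standardized variables, PC1 explains (1 + |r|) / 2."""
        rng = np.random.default_rng(5)
        a = rng.normal(size=30)
        b = 0.6 * a + rng.normal(size=30)
        df = dg.scale_features(pd.DataFrame({"a": a, "b": b}))
        r = np.corrcoef(df["a"], df["b"])[0, 1]
        res = dg.pca(df)
        assert res.explained_variance_fraction[0] == pytest.approx(
            (1 + abs(r)) / 2, abs=1e-9
        )

    def test_row_replication_leaves_loadings_unchanged(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(6, 3)))
        doubled = pd.concat([df, df], ignore_index=True)
        l1 = dg.pca(dg.scale_features(df)).loadings
        l2 = dg.pca(dg.scale_features(doubled)).loadings
        assert np.allclose(l1.to_numpy(), l2.to_numpy(), atol=1e-9)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(9)
        df = dg.scale_features(pd.DataFrame(rng.normal(size=(9, 4))))
        res = dg.pca(df)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, df.to_numpy() - df.to_numpy().mean(0), atol=1e-9)

    def test_loadings_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(10)
        df = dg.scale_features(pd.DataFrame(rng.normal(size=(12, 5))))
        L = dg.pca(df).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)
        for k in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, k])), k] > 0

    def test_rank_deficiency_truncates_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        with pytest.warns(UserWarning, match="rank"):
            res = dg.pca(df)
        assert res.scores.shape[1] == 1


class TestPearsonScan:
    def test_perfect_correlations(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        df["up"] = 2 * df["x"] + 1
        df["down"] = -df["x"]
        out = dg.pearson_scan(df, [("x", "up"), ("x", "down")])
        assert out["r"].tolist() == pytest.approx([1.0, -1.0])

    def test_definitional_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.5, 7.0, 9.0])
        y = np.array([2.0, 1.5, 3.0, 5.0, 4.5, 8.0])
        n = len(x)
        r_def = ((x * y).sum() - n * x.mean() * y.mean()) / (
            np.sqrt((x**2).sum() - n * x.mean() ** 2)
            * np.sqrt((y**2).sum() - n * y.mean() ** 2)
        )
        t = r_def * np.sqrt((n - 2) / (1 - r_def**2))
        p_def = 2 * sps.t.sf(abs(t), n - 2)
        out = dg.pearson_scan(pd.DataFrame({"x": x, "y": y}), [("x", "y")])
        assert out.loc[0, "r"] == pytest.approx(r_def, abs=1e-12)
        assert out.loc[0, "p"] == pytest.approx(p_def, rel=1e-9)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"a": rng.normal(size=10)})
        df["b"] = rng.normal(size=10)
        df["b_scaled"] = 3.5 * df["b"] - 2.0
        out = dg.pearson_scan(df, [("a", "b"), ("b", "a"), ("a", "b_scaled")])
        assert out.loc[0, "r"] == pytest.approx(out.loc[1, "r"], abs=1e-12)
        assert out.loc[0, "r"] == pytest.approx(out.loc[2, "r"], abs=1e-12)

    def test_zero_variance_reported_missing(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        out = dg.pearson_scan(df, [("a", "b")])
        assert np.isnan(out.loc[0, "r"])

    def test_pairwise_complete_observations(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, np.nan, 5.0], "b": [1.0, 2.1, 2.9, 4.0, np.nan]}
        )
        out = dg.pearson_scan(df, [("a", "b")])
        assert out.loc[0, "n"] == 3


class TestEnzymeNormalization:
    def test_examples(self):
        assert dg.normalize_enzyme_activity([2.0, 4.0, 8.0]) == pytest.approx(
            [0.25, 0.5, 1.0]
        )
        assert dg.normalize_enzyme_activity([3.7]) == [1.0]

    def test_max_is_always_one(self):
        rng = np.random.default_rng(12)
        vals = list(rng.uniform(0.1, 50.0, size=9))
        assert max(dg.normalize_enzyme_activity(vals)) == pytest.approx(1.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            dg.normalize_enzyme_activity([0.0, 0.0])
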