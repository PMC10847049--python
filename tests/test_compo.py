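import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.composition import clr as skbio_clr

import stressvirome as sv
from stressvirome.compo import (
    aitchison_distances,
    clr_transform,
    hill_alpha,
    min_count_filter,
    pca_on_clr,
    permanova,
    prevalence_filter,
    zero_replace_const,
)
from stressvirome.model import AbundanceMatrix, ValidationError


def counts_matrix(arr, features=None, samples=None):
    arr = np.asarray(arr)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return AbundanceMatrix(pd.DataFrame(arr, index=features, columns=samples), "count")


class TestFilters:
    def test_min_count_boundary(self):
        m = counts_matrix([[4, 0], [5, 0], [60, 40]])
        out = min_count_filter(m, 5)
        assert out.feature_ids == ["f1", "f2"]

    def test_min_count_zero_is_identity(self):
        m = counts_matrix([[0, 1], [2, 3]])
        assert min_count_filter(m, 0).feature_ids == m.feature_ids

    def test_prevalence_boundary(self):
        arr = np.zeros((3, 6), dtype=int)
        arr[0, :2] = 1          # 2/6 -> removed
        arr[1, :3] = 1          # 3/6 -> kept (boundary)
        arr[2, :] = 1           # kept
        out = prevalence_filter(counts_matrix(arr), 0.5)
        assert out.feature_ids == ["f1", "f2"]


class TestZeroReplace:
    def test_const_rule(self):
        m = counts_matrix([[0, 2], [4, 0]])
        out = zero_replace_const(m, 0.65)
        assert out.values.loc["f0", "s0"] == pytest.approx(1.3)
        assert out.values.loc["f1", "s0"] == 4

    def test_no_zeros_identity(self):
        m = counts_matrix([[1, 2], [3, 4]])
        pd.testing.assert_frame_equal(zero_replace_const(m).values, m.values.astype(float))

    def test_factor_one_equals_minimum(self):
        m = counts_matrix([[0, 2], [4, 3]])
        assert zero_replace_const(m, 1.0).values.loc["f0", "s0"] == 2

    def test_all_zero_error(self):
        with pytest.raises(ValidationError):
            zero_replace_const(counts_matrix([[0, 0]]))


class TestClr:
    def test_uniform_composition_maps_to_zero(self):
        m = counts_matrix([[1], [1], [1], [1]])
        np.testing.assert_allclose(clr_transform(m).values.to_numpy(), 0.0)

    def test_hand_computed_values(self):
        m = counts_matrix([[2], [4], [8]])
        expected = [np.log(0.5), 0.0, np.log(2.0)]
        np.testing.assert_allclose(
            clr_transform(m).values["s0"].to_numpy(), expected, atol=1e-12
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.1, 10, size=(5, 3))
        a = clr_transform(counts_matrix(x)).values.to_numpy()
        b = clr_transform(counts_matrix(x * [2.0, 5.0, 0.1])).values.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_nonpositive_error(self):
        with pytest.raises(ValidationError):
            clr_transform(counts_matrix([[0, 1]]))

    def test_matches_skbio(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.1, 10, size=(6, 4))
        ours = clr_transform(counts_matrix(x)).values.to_numpy()
        reference = skbio_clr(x.T).T
        np.testing.assert_allclose(ours, reference, atol=1e-12)

    def test_columns_sum_to_zero(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.1, 10, size=(30, 8))
        sums = clr_transform(counts_matrix(x)).values.sum(axis=0).to_numpy()
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)


class TestAitchison:
    def test_identical_samples_distance_zero(self):
        m = counts_matrix([[1, 1], [2, 2]])
        d = aitchison_distances(clr_transform(m))
        assert d["s0", "s1"] == 0.0

    def test_compositional_invariance(self):
        m = counts_matrix([[1, 2], [2, 4], [3, 6]])  # s1 = 2 x s0
        d = aitchison_distances(clr_transform(m))
        assert d["s0", "s1"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_euclidean(self):
        clr = AbundanceMatrix(
            pd.DataFrame({"s0": [0.0, 0.0], "s1": [3.0, -3.0]}, index=["f0", "f1"]),
            "clr",
        )
        assert aitchison_distances(clr)["s0", "s1"] == pytest.approx(np.sqrt(18))

    def test_single_sample_error(self):
        clr = AbundanceMatrix(pd.DataFrame({"s0": [0.0, 0.0]}, index=["a", "b"]), "clr")
        with pytest.raises(ValidationError):
            aitchison_distances(clr)


class TestPermanova:
    def _dm(self, X):
        return DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(len(X))])

    def test_perfect_separation(self):
        # groups large enough that no permutation reproduces the exact split
        X = np.array([[0.0, 0]] * 8 + [[10.0, 0]] * 8)
        res = permanova(self._dm(X), ["A"] * 8 + ["B"] * 8, n_permutations=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_degenerate_identical_samples(self):
        X = np.zeros((6, 2))
        res = permanova(self._dm(X), ["A"] * 3 + ["B"] * 3, n_permutations=99, seed=0)
        assert res.p_value == 1.0

    def test_single_group_error(self):
        X = np.random.default_rng(0).normal(size=(4, 2))
        with pytest.raises(ValidationError):
            permanova(self._dm(X), ["A"] * 4)

    def test_r_squared_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            X = rng.normal(size=(n, 3))
            labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
            d = squareform(pdist(X))
            res = permanova(self._dm(X), labels, n_permutations=9, seed=1)
            d2 = d ** 2
            sst = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
            ssw = 0.0
            for g in ("A", "B"):
                idx = [i for i in range(n) if labels[i] == g]
                ssw += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
            assert res.r_squared == pytest.approx(1 - ssw / sst, abs=1e-10)

    def test_pseudo_f_matches_skbio(self):
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        labels = ["A"] * 6 + ["B"] * 6
        ours = permanova(self._dm(X), labels, n_permutations=49, seed=0)
        ref = skbio_permanova(self._dm(X), grouping=labels, permutations=49)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 4))
        labels = ["A"] * 5 + ["B"] * 5
        r1 = permanova(self._dm(X), labels, n_permutations=99, seed=11)
        r2 = permanova(self._dm(X), labels, n_permutations=99, seed=11)
        assert r1 == r2


class TestPca:
    def test_two_samples_pc1_explains_everything(self):
        m = AbundanceMatrix(
            pd.DataFrame({"s0": [1.0, -1.0], "s1": [-1.0, 1.0]}, index=["a", "b"]), "clr"
        )
        _, frac = pca_on_clr(m)
        assert frac[0] == pytest.approx(1.0)

    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(4, 3))
        x -= x.mean(axis=0)
        df = pd.DataFrame(
            np.hstack([x, x[:, [0]]]), index=list("abcd"), columns=["s0", "s1", "s2", "s0b"]
        )
        scores, _ = pca_on_clr(AbundanceMatrix(df - df.mean(axis=0), "clr"))
        np.testing.assert_allclose(
            scores.loc["s0"].to_numpy(), scores.loc["s0b"].to_numpy(), atol=1e-9
        )

    def test_explained_variance_sums_to_one(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(10, 6))
        x -= x.mean(axis=0)
        _, frac = pca_on_clr(AbundanceMatrix(pd.DataFrame(x), "clr"))
        assert frac.sum() == pytest.approx(1.0)


class TestHillNumbers:
    @pytest.mark.parametrize("q", [0, 1, 2])
    def test_uniform_equals_richness(self, q):
        assert hill_alpha([5, 5, 5, 5], q) == pytest.approx(4.0)

    @pytest.mark.parametrize("q", [0, 1, 2])
    def test_single_feature_is_one(self, q):
        assert hill_alpha([0, 9, 0], q) == pytest.approx(1.0)

    def test_hand_computed_orders(self):
        p = [0.5, 0.25, 0.25]
        assert hill_alpha(p, 1) == pytest.approx(np.exp(1.5 * np.log(2)))
        assert hill_alpha(p, 2) == pytest.approx(1 / 0.375)

    def test_zero_total_error(self):
        with pytest.raises(ValidationError):
            hill_alpha([0, 0], 1)

    def test_evening_transfer_does_not_decrease_diversity(self):
        # move mass from the most to the least abundant feature
        before = np.array([10.0, 6.0, 2.0])
        after = np.array([9.0, 6.0, 3.0])
        for q in (1, 2):
            assert hill_alpha(after, q) >= hill_alpha(before, q)
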