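import itertools

import numpy as np
import pandas as pd
import pytest

from oxynet import multivar
from oxynet.errors import DataError


def mat(cols: dict) -> pd.DataFrame:
    """taxa x samples matrix from {sample: values}."""
    return pd.DataFrame(cols, index=[f"t{i}" for i in range(len(next(iter(cols.values()))))])


class TestDissimilarity:
    def test_bray_curtis_hand_values(self):
        m = mat({"a": [1, 2], "b": [2, 1], "c": [1, 2], "d": [0, 0], "e": [0, 0]})
        d = multivar.bray_curtis(m).values
        assert d.loc["a", "b"] == pytest.approx(1 / 3)
        assert d.loc["a", "c"] == 0.0
        assert d.loc["d", "e"] == 0.0  # all-zero pair defined as identical
        m2 = mat({"a": [1, 0], "b": [0, 1]})
        assert multivar.bray_curtis(m2).values.loc["a", "b"] == 1.0

    def test_jaccard_set_arithmetic(self):
        m = pd.DataFrame(
            {"s1": [5, 1, 2, 0], "s2": [0, 3, 9, 4], "s3": [5, 1, 2, 0]},
            index=list("ABCD"),
        )
        d = multivar.jaccard(m).values
        assert d.loc["s1", "s2"] == pytest.approx(1 - 2 / 4)  # {A,B,C} vs {B,C,D}
        assert d.loc["s1", "s3"] == 0.0

    def test_negative_entries_rejected(self):
        with pytest.raises(DataError):
            multivar.bray_curtis(mat({"a": [1, -1], "b": [0, 1]}))

    def test_matrix_invariants(self, dataset):
        d = multivar.bray_curtis(dataset.abundance).values.to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()


def naive_anosim_r(dist: np.ndarray, labels: np.ndarray) -> float:
    """Straightforward textbook R for the oracle (independent of the engine)."""
    from scipy.stats import rankdata

    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    vals = np.array([dist[i, j] for i, j in pairs])
    ranks = rankdata(vals)
    within = np.array([labels[i] == labels[j] for i, j in pairs])
    return (ranks[~within].mean() - ranks[within].mean()) / (len(pairs) / 2)


def exact_anosim_p(dist: np.ndarray, labels: np.ndarray) -> float:
    """Brute-force enumeration over all distinct relabellings."""
    r_obs = naive_anosim_r(dist, labels)
    n = len(labels)
    n1 = int((labels == labels[0]).sum())
    count = total = 0
    for subset in itertools.combinations(range(n), n1):
        lab = np.ones(n, dtype=int)
        lab[list(subset)] = 0
        r = naive_anosim_r(dist, lab)
        total += 1
        count += r >= r_obs - 1e-12
    return count / total


class TestAnosim:
    def make(self, seed, n=8, shift=0.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 4))
        labels = np.array([0] * (n // 2) + [1] * (n - n // 2))
        x[labels == 1] += shift
        frame = pd.DataFrame(np.abs(x).T, columns=[f"s{i}" for i in range(n)])
        return multivar.bray_curtis(frame), pd.Series(labels, index=frame.columns)

    def test_maximal_separation_gives_r_one(self):
        m = mat({"a": [9, 8, 0, 0], "b": [8, 9, 0, 0], "c": [0, 0, 9, 8], "d": [0, 0, 8, 9]})
        res = multivar.anosim(multivar.bray_curtis(m), pd.Series([0, 0, 1, 1], index=m.columns), 999, 0)
        assert res.r == pytest.approx(1.0)

    def test_null_r_is_small(self):
        dist, groups = self.make(seed=5, shift=0.0)
        res = multivar.anosim(dist, groups, 999, 0)
        assert abs(res.r) < 0.5 and res.p > 0.05

    def test_exact_p_matches_enumeration_oracle(self):
        for seed in range(5):
            dist, groups = self.make(seed, n=6, shift=1.0)
            res = multivar.anosim(dist, groups, permutations=9999, seed=0)
            assert res.method == "exact"
            oracle = exact_anosim_p(dist.values.to_numpy(), groups.to_numpy())
            assert res.p == pytest.approx(oracle, abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        dist, groups = self.make(seed=2, n=10, shift=0.8)
        res1 = multivar.anosim(dist, groups, 999, 7)
        squashed = multivar.DissimilarityMatrix(dist.values ** 3, dist.metric)
        res2 = multivar.anosim(squashed, groups, 999, 7)
        assert res1.r == pytest.approx(res2.r)
        assert res1.p == pytest.approx(res2.p)

    def test_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        dist, groups = self.make(seed=3, n=12, shift=1.0)
        res = multivar.anosim(dist, groups, 999, 0)
        sk = skbio_stats.anosim(
            skbio_stats.DistanceMatrix(dist.values.to_numpy(), ids=list(dist.ids)),
            grouping=[str(g) for g in groups],
            permutations=0,
        )
        assert res.r == pytest.approx(sk["test statistic"], abs=1e-12)

    def test_singleton_group_rejected(self):
        m = mat({"a": [1, 2], "b": [2, 1], "c": [3, 1]})
        with pytest.raises(DataError, match="singleton"):
            multivar.anosim(multivar.bray_curtis(m), pd.Series([0, 0, 1], index=m.columns), 99, 0)


class TestBalanceGroups:
    def test_padding_to_largest_group(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.uniform(size=(4, 8)), columns=[f"s{i}" for i in range(8)])
        groups = pd.Series(["a"] * 5 + ["b"] * 3, index=m.columns)
        bal, bgroups, padded = multivar.balance_groups(m, groups)
        assert sorted(bgroups.value_counts()) == [5, 5]
        assert len(padded) == 2
        b_mean = m.loc[:, groups[groups == "b"].index].mean(axis=1)
        for label in padded:
            pd.testing.assert_series_equal(bal[label], b_mean, check_names=False)
        # padding preserves the group mean
        bal_mean = bal.loc[:, bgroups[bgroups == "b"].index].mean(axis=1)
        pd.testing.assert_series_equal(bal_mean, b_mean, check_names=False)

    def test_already_balanced_identity(self):
        m = mat({"a": [1, 2], "b": [2, 1], "c": [3, 1], "d": [1, 3]})
        bal, _, padded = multivar.balance_groups(m, pd.Series([0, 0, 1, 1], index=m.columns))
        assert padded == []
        pd.testing.assert_frame_equal(bal, m)

    def test_single_sample_group_replicates_itself(self):
        m = mat({"a": [1, 2], "b": [2, 1], "c": [3, 1]})
        bal, _, padded = multivar.balance_groups(m, pd.Series([0, 0, 1], index=m.columns))
        assert len(padded) == 1
        pd.testing.assert_series_equal(
            bal[padded[0]], m["c"].astype(float), check_names=False
        )


class TestSimper:
    def test_single_taxon_contributes_everything(self):
        m = pd.DataFrame({"a": [3.0], "b": [9.0]}, index=["only"])
        res = multivar.simper(m, pd.Series([0, 1], index=m.columns))
        assert res.table.loc["only", "percent"] == pytest.approx(100.0)

    def test_symmetric_toy_splits_evenly(self):
        m = pd.DataFrame({"a": [10.0, 0.0], "b": [0.0, 10.0]}, index=["t1", "t2"])
        res = multivar.simper(m, pd.Series([0, 1], index=m.columns))
        assert res.table["percent"].tolist() == pytest.approx([50.0, 50.0])
        assert res.average_dissimilarity == pytest.approx(1.0)

    def test_contributions_sum_to_bray_curtis(self, dataset):
        m = dataset.abundance.iloc[:, :6]
        groups = pd.Series([0, 0, 0, 1, 1, 1], index=m.columns)
        res = multivar.simper(m, groups)
        d = multivar.bray_curtis(m).values
        between = [d.loc[j, k] for j in m.columns[:3] for k in m.columns[3:]]
        assert res.average_dissimilarity == pytest.approx(np.mean(between))
        assert res.table["percent"].sum() == pytest.approx(100.0, abs=1e-6)


class TestNmds:
    def planar_distances(self, seed=0, n=8):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(size=(n, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(n)]
        return multivar.DissimilarityMatrix(pd.DataFrame(d, index=ids, columns=ids), "euclid")

    def test_recoverable_planar_geometry(self):
        res = multivar.nmds(self.planar_distances(), restarts=20, seed=0,
                            max_iter=1000, tol=1e-9)
        assert res.stress < 1e-3

    def test_duplicate_samples_coincide(self):
        d = self.planar_distances(seed=1, n=6).values
        d.iloc[0, 1] = d.iloc[1, 0] = 0.0  # force duplicates
        res = multivar.nmds(multivar.DissimilarityMatrix(d, "euclid"), restarts=8, seed=0)
        gap = np.linalg.norm(res.coordinates.iloc[0] - res.coordinates.iloc[1])
        spread = res.coordinates.std().mean()
        assert gap < 0.05 * spread

    def test_small_sample_rejected(self):
        d = self.planar_distances(n=2)
        with pytest.raises(DataError):
            multivar.nmds(d)
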