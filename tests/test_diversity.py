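import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as skbio_faith_pd

from jumpsieve import (
    InputError,
    PreconditionError,
    beta_multisite,
    beta_pairwise,
    beta_resample,
    depth_residuals,
    exclusive_otus,
    faith_pd,
    richness,
    to_presence_absence,
)

TOY_TREE = "((A:1,B:1):1,C:2);"


def pa_matrix(rows, columns=None):
    df = pd.DataFrame(rows)
    if columns is not None:
        df.columns = columns
    return df.astype(bool)


def brute_force_multisite(sets):
    """Independent implementation of the multi-site Sorensen partition
    working directly on Python sets."""
    s_i = [len(s) for s in sets]
    s_t = len(set().union(*sets))
    core = sum(s_i) - s_t
    mins = maxs = 0
    for a, b in itertools.combinations(sets, 2):
        b_ij, b_ji = len(a - b), len(b - a)
        mins += min(b_ij, b_ji)
        maxs += max(b_ij, b_ji)
    sim = mins / (core + mins) if core + mins else 0.0
    sor = (mins + maxs) / (2 * core + mins + maxs) if core + mins + maxs else 0.0
    return sor, sim, sor - sim


class TestRichness:
    def test_counts_positive_cells(self):
        cm = pd.DataFrame({"o1": [3, 0], "o2": [0, 0], "o3": [7, 1]},
                          index=["s1", "s2"])
        assert richness(cm).tolist() == [2, 1]

    def test_empty_sample_is_zero(self):
        cm = pd.DataFrame({"o1": [0], "o2": [0]}, index=["s1"])
        assert richness(cm).tolist() == [0]

    def test_abundance_invariance(self):
        cm = pd.DataFrame({"o1": [3, 10], "o2": [0, 999]}, index=["s1", "s2"])
        assert richness(cm).equals(richness(to_presence_absence(cm).astype(int)))


class TestFaithPD:
    def test_root_inclusive_toy_values(self):
        cm = pd.DataFrame(
            {"A": [1, 1, 1], "B": [1, 0, 1], "C": [0, 0, 1]},
            index=["ab", "a", "abc"],
        )
        pd_vals = faith_pd(cm, TOY_TREE)
        assert pd_vals["ab"] == pytest.approx(3.0)   # A + B + shared internal
        assert pd_vals["a"] == pytest.approx(2.0)    # A + path to root
        assert pd_vals["abc"] == pytest.approx(5.0)  # whole tree

    def test_root_exclusion_drops_basal_path(self):
        cm = pd.DataFrame({"A": [1], "B": [1], "C": [0]}, index=["ab"])
        assert faith_pd(cm, TOY_TREE, include_root=False)["ab"] == pytest.approx(2.0)

    def test_empty_sample_gets_zero(self):
        cm = pd.DataFrame({"A": [0], "B": [0], "C": [0]}, index=["none"])
        assert faith_pd(cm, TOY_TREE)["none"] == 0.0

    def test_missing_tip_rejected(self):
        cm = pd.DataFrame({"A": [1], "Z": [1]}, index=["s"])
        with pytest.raises(InputError, match="Z"):
            faith_pd(cm, TOY_TREE)

    def _random_tree(self, rng, names):
        # random caterpillar; the root carries no branch length
        nwk = f"{names[0]}:{rng.integers(1, 5)}"
        for nm in names[1:-1]:
            nwk = f"({nwk},{nm}:{rng.integers(1, 5)}):{rng.integers(1, 4)}"
        return f"({nwk},{names[-1]}:{rng.integers(1, 5)});"

    def test_matches_scikit_bio_on_random_trees(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 10))
            names = [f"t{i}" for i in range(n)]
            nwk = self._random_tree(rng, names)
            present = rng.random(n) < 0.6
            if not present.any():
                present[0] = True
            cm = pd.DataFrame([present.astype(int)], columns=names, index=["s"])
            ours = faith_pd(cm, nwk)["s"]
            ref = skbio_faith_pd(
                present.astype(int), taxa=names, tree=TreeNode.read([nwk])
            )
            assert ours == pytest.approx(float(ref))

    def test_monotone_under_taxon_addition_and_bounded(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 9))
            names = [f"t{i}" for i in range(n)]
            nwk = self._random_tree(rng, names)
            tree = TreeNode.read([nwk])
            total = sum(node.length or 0 for node in tree.traverse(include_self=False))
            present = np.zeros(n, dtype=int)
            order = rng.permutation(n)
            last = 0.0
            for k in order:
                present[k] = 1
                cm = pd.DataFrame([present], columns=names, index=["s"])
                val = faith_pd(cm, nwk)["s"]
                assert val >= last - 1e-12
                assert val <= total + 1e-12
                last = val


class TestDepthResiduals:
    def test_perfect_linearity_gives_zero_raw_residuals(self):
        vals = pd.Series([10.0, 20.0, 30.0])
        depths = pd.Series([1000.0, 2000.0, 3000.0])
        raw = depth_residuals(vals, depths, zscore=False)
        assert np.allclose(raw, 0.0, atol=1e-10)

    def test_residuals_sum_to_zero(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 40))
            vals = pd.Series(rng.uniform(0, 100, n))
            depths = pd.Series(rng.uniform(1, 1e5, n))
            raw = depth_residuals(vals, depths, zscore=False)
            assert abs(raw.sum()) < 1e-8

    def test_zscored_mean_zero_unit_variance(self, rng):
        vals = pd.Series(rng.uniform(0, 50, 25))
        depths = pd.Series(rng.uniform(1, 1e4, 25))
        z = depth_residuals(vals, depths)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_sample_above_fit_has_positive_residual(self):
        # last sample has more richness than its depth predicts
        vals = pd.Series([10.0, 20.0, 30.0, 45.0])
        depths = pd.Series([1000.0, 2000.0, 3000.0, 3500.0])
        raw = depth_residuals(vals, depths, zscore=False)
        assert raw.iloc[-1] > 0

    def test_constant_depth_policy(self):
        vals = pd.Series([1.0, 2.0, 3.0])
        depths = pd.Series([10.0, 10.0, 10.0])
        with pytest.raises(PreconditionError):
            depth_residuals(vals, depths)
        centered = depth_residuals(vals, depths, zscore=False,
                                   on_constant_depth="center")
        assert np.allclose(centered, [-1, 0, 1])


class TestBetaPairwise:
    def test_turnover_only_pair(self):
        pa = pa_matrix({"a": [1, 0], "b": [1, 1], "c": [1, 1], "d": [0, 1]})
        part = beta_pairwise(pa, 0, 1)
        assert part.beta_sor == pytest.approx(1 / 3)
        assert part.beta_sim == pytest.approx(1 / 3)
        assert part.beta_sne == pytest.approx(0.0)

    def test_perfectly_nested_pair_is_pure_nestedness(self):
        pa = pa_matrix({"a": [1, 1], "b": [1, 1], "c": [1, 0], "d": [1, 0]})
        part = beta_pairwise(pa, 0, 1)
        assert part.beta_sim == 0.0
        assert part.beta_sor == pytest.approx(1 / 3)
        assert part.beta_sne == pytest.approx(1 / 3)

    def test_identical_samples_have_zero_dissimilarity(self):
        pa = pa_matrix({"a": [1, 1], "b": [1, 1]})
        part = beta_pairwise(pa, 0, 1)
        assert (part.beta_sor, part.beta_sim, part.beta_sne) == (0.0, 0.0, 0.0)

    def test_both_empty_rejected(self):
        pa = pa_matrix({"a": [0, 0]})
        with pytest.raises(PreconditionError):
            beta_pairwise(pa, 0, 1)


class TestBetaMultisite:
    def test_two_sites_reduce_to_pairwise(self, rng):
        for _ in range(20):
            x = rng.random((2, 12)) < 0.5
            if not (x[0].any() or x[1].any()):
                continue
            pa = pd.DataFrame(x)
            pair = beta_pairwise(pa, 0, 1)
            multi = beta_multisite(pa)
            assert multi.beta_sor == pytest.approx(pair.beta_sor)
            assert multi.beta_sim == pytest.approx(pair.beta_sim)

    def test_identical_sites_have_zero_beta(self):
        pa = pa_matrix([[1, 0, 1]] * 4)
        part = beta_multisite(pa)
        assert part.beta_sor == 0.0 and part.beta_sne == 0.0

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(200):
            n_sites = int(rng.integers(2, 7))
            n_otus = int(rng.integers(2, 15))
            x = rng.random((n_sites, n_otus)) < rng.uniform(0.2, 0.8)
            if not x.any():
                continue
            part = beta_multisite(pd.DataFrame(x))
            sets = [set(np.nonzero(row)[0]) for row in x]
            sor, sim, sne = brute_force_multisite(sets)
            assert part.beta_sor == pytest.approx(sor)
            assert part.beta_sim == pytest.approx(sim)
            assert part.beta_sne == pytest.approx(sne)

    def test_partition_identity_holds_everywhere(self, rng):
        for _ in range(300):
            n_sites = int(rng.integers(2, 8))
            x = rng.random((n_sites, 10)) < 0.5
            if not x.any():
                continue
            pa = pd.DataFrame(x)
            multi = beta_multisite(pa)
            assert multi.beta_sor == pytest.approx(
                multi.beta_sim + multi.beta_sne, abs=1e-12
            )
            assert 0 <= multi.beta_sim <= multi.beta_sor <= 1


class TestBetaResample:
    def make_pa(self, rng, n=12, otus=20):
        x = rng.random((n, otus)) < 0.5
        x[:, 0] = True  # no all-empty rows
        return pd.DataFrame(x, index=[f"s{i}" for i in range(n)])

    def test_group_of_exactly_n_sites_has_constant_draws(self, rng):
        pa = self.make_pa(rng, n=6)
        groups = pd.Series(["g1"] * 6, index=pa.index)
        with pytest.warns(UserWarning, match="resampling at group size"):
            dists = beta_resample(pa, groups, n_sites=20, n_iter=30, seed=1)
        full = beta_multisite(pa)
        draws = dists["g1"].to_frame()
        assert np.allclose(draws["beta_sor"], full.beta_sor)
        assert np.allclose(draws["beta_sne"], full.beta_sne)

    def test_same_seed_reproduces_draws(self, rng):
        pa = self.make_pa(rng, n=14)
        groups = pd.Series(["g1"] * 7 + ["g2"] * 7, index=pa.index)
        a = beta_resample(pa, groups, n_sites=5, n_iter=50, seed=3)
        b = beta_resample(pa, groups, n_sites=5, n_iter=50, seed=3)
        for g in a:
            pd.testing.assert_frame_equal(a[g].to_frame(), b[g].to_frame())

    def test_monte_carlo_means_stabilize_across_seeds(self, rng):
        pa = self.make_pa(rng, n=16, otus=30)
        groups = pd.Series(["g"] * 16, index=pa.index)
        means = [
            beta_resample(pa, groups, n_sites=8, n_iter=400, seed=s)["g"].mean()[
                "beta_sor"
            ]
            for s in (11, 22, 33)
        ]
        assert np.std(means) < 0.01  # well within Monte-Carlo error

    def test_mean_pairwise_alternative_statistic(self, rng):
        pa = self.make_pa(rng, n=6)
        groups = pd.Series(["g"] * 6, index=pa.index)
        dists = beta_resample(pa, groups, n_sites=6, n_iter=3, seed=1,
                              statistic="mean_pairwise")
        expected = np.mean(
            [beta_pairwise(pa, i, j).beta_sor
             for i, j in itertools.combinations(pa.index, 2)]
        )
        assert dists["g"].to_frame()["beta_sor"].iloc[0] == pytest.approx(expected)


class TestExclusiveOtus:
    def test_disjoint_groups_share_nothing(self):
        pa = pa_matrix({"a": [1, 0], "b": [1, 0], "c": [0, 1]})
        pa.index = ["s1", "s2"]
        groups = pd.Series(["g1", "g2"], index=pa.index)
        out = exclusive_otus(pa, groups)
        assert out["exclusive"] == {"g1": 2, "g2": 1}
        assert "g1&g2" not in out["regions"]

    def test_identical_groups_share_everything(self):
        pa = pa_matrix({"a": [1, 1], "b": [1, 1]})
        pa.index = ["s1", "s2"]
        groups = pd.Series(["g1", "g2"], index=pa.index)
        out = exclusive_otus(pa, groups)
        assert out["exclusive"] == {"g1": 0, "g2": 0}
        assert out["regions"] == {"g1&g2": 2}

    def test_three_groups_match_per_otu_enumeration(self, rng):
        n, otus = 9, 25
        x = rng.random((n, otus)) < 0.4
        pa = pd.DataFrame(x, index=[f"s{i}" for i in range(n)])
        groups = pd.Series(
            ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3, index=pa.index
        )
        out = exclusive_otus(pa, groups)
        # independent per-OTU enumeration
        regions = {}
        for o in range(otus):
            key = "&".join(
                g for g in ["g1", "g2", "g3"] if pa.loc[groups == g, o].any()
            )
            if key:
                regions[key] = regions.get(key, 0) + 1
        assert out["regions"] == regions
        pooled = int(pa.any(axis=0).sum())
        assert sum(out["regions"].values()) == pooled
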