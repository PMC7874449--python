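"""Distance conversion, Ward tree, PERMANOVA, recursive partition."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from guildflow.containers import FeatureTable
from guildflow.correlation import CorrelationMatrix
from guildflow.guilds import (
    DistanceMatrix,
    GuildPartition,
    GuildPartitioner,
    corr_to_dist,
    guild_abundance,
    partition_guilds,
    permanova,
    ward_tree,
)
from guildflow.synthetic import planted_two_clade_distance


def dist_from(d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix([f"f{i}" for i in range(d.shape[0])], d)


def brute_force_permanova_p(d, mask):
    """Independent oracle: enumerate every relabeling in plain Python."""
    N = d.shape[0]
    n1 = int(mask.sum())

    def f_stat(group_a):
        in_a = [i in group_a for i in range(N)]
        ss_tot = sum(d[i][j] ** 2 for i in range(N) for j in range(i + 1, N)) / N
        ss_a = sum(
            d[i][j] ** 2
            for i in range(N)
            for j in range(i + 1, N)
            if in_a[i] and in_a[j]
        ) / n1
        ss_b = sum(
            d[i][j] ** 2
            for i in range(N)
            for j in range(i + 1, N)
            if not in_a[i] and not in_a[j]
        ) / (N - n1)
        ss_w = ss_a + ss_b
        if ss_w == 0:
            return math.inf if ss_tot > 0 else 0.0
        return (ss_tot - ss_w) / (ss_w / (N - 2))

    f_obs = f_stat(set(np.flatnonzero(mask)))
    count = total = 0
    for group_a in combinations(range(N), n1):
        total += 1
        if f_stat(set(group_a)) >= f_obs - 1e-12:
            count += 1
    return count / total


class TestCorrToDist:
    def test_endpoint_mapping(self):
        r = np.array([[1.0, 1.0, 0.0, -1.0],
                      [1.0, 1.0, 0.5, 0.0],
                      [0.0, 0.5, 1.0, 0.25],
                      [-1.0, 0.0, 0.25, 1.0]])
        dm = corr_to_dist(CorrelationMatrix(list("abcd"), r, "spearman_plain"))
        assert dm.d[0, 1] == 0.0      # r = 1
        assert dm.d[0, 2] == 1.0      # r = 0
        assert dm.d[0, 3] == 2.0      # r = -1
        assert np.all(np.diag(dm.d) == 0.0)


class TestWardTree:
    def test_duplicated_features_merge_first_at_zero(self):
        d = np.array([[0, 0, 1.5], [0, 0, 1.5], [1.5, 1.5, 0]], dtype=float)
        tree = ward_tree(dist_from(d))
        assert tree.Z[0, 2] == 0.0
        assert sorted(tree.members(3)) == [0, 1]

    def test_two_perfect_pairs_topology(self):
        # (A,B) and (C,D): within-pair d=0, between d=2
        d = np.full((4, 4), 2.0)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        np.fill_diagonal(d, 0.0)
        tree = ward_tree(dist_from(d))
        node_sets = {frozenset(tree.members(n)) for n in range(4, 7)}
        assert frozenset({0, 1}) in node_sets
        assert frozenset({2, 3}) in node_sets
        # pair merges sit strictly below the root merge
        assert tree.Z[0, 2] < tree.Z[2, 2] and tree.Z[1, 2] < tree.Z[2, 2]

    def test_order_invariance_of_member_sets(self):
        rng = np.random.default_rng(0)
        n = 12
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = rng.uniform(0.1, 1.9, len(iu[0]))
        d = d + d.T
        tree = ward_tree(dist_from(d))
        perm = rng.permutation(n)
        dm_p = DistanceMatrix([f"f{i}" for i in perm], d[np.ix_(perm, perm)])
        tree_p = ward_tree(dm_p)
        sets = {
            frozenset(tree.feature_ids[i] for i in tree.members(node))
            for node in range(n, 2 * n - 1)
        }
        sets_p = {
            frozenset(tree_p.feature_ids[i] for i in tree_p.members(node))
            for node in range(n, 2 * n - 1)
        }
        assert sets == sets_p

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(1)
        n = 10
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = rng.uniform(0.0, 2.0, len(iu[0]))
        d = d + d.T
        tree = ward_tree(dist_from(d))
        heights = tree.Z[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_non_finite_distance_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            dist_from(d)

    def test_newick_roundtrip_leaf_names(self):
        d = np.array([[0, 0.4, 1.8], [0.4, 0, 1.6], [1.8, 1.6, 0]], dtype=float)
        nwk = ward_tree(dist_from(d)).to_newick()
        assert nwk.endswith(";")
        for name in ("f0", "f1", "f2"):
            assert name in nwk


class TestPermanova:
    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            N = int(rng.integers(4, 9))
            d = np.zeros((N, N))
            iu = np.triu_indices(N, 1)
            d[iu] = rng.uniform(0.05, 2.0, len(iu[0]))
            d = d + d.T
            n1 = int(rng.integers(1, N))
            mask = np.zeros(N, dtype=bool)
            mask[rng.permutation(N)[:n1]] = True
            res = permanova(d, mask.astype(int), n_perm=10_000)
            assert res.exhaustive
            assert res.p_value == pytest.approx(brute_force_permanova_p(d, mask))

    def test_pseudo_f_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(6)
        N = 12
        d = np.zeros((N, N))
        iu = np.triu_indices(N, 1)
        d[iu] = rng.uniform(0.1, 2.0, len(iu[0]))
        d = d + d.T
        labels = np.array([0] * 5 + [1] * 7)
        mine = permanova(d, labels, n_perm=99, seed=0)
        theirs = sk_permanova(SkDM(d), grouping=[str(x) for x in labels], permutations=9)
        assert mine.pseudo_F == pytest.approx(float(theirs["test statistic"]), rel=1e-10)

    def test_separated_groups_exact_p(self):
        # 3v3, within 0.1, between 1.9: only the true labeling and its
        # complement reach the max F among the C(6,3)=20 relabelings
        d = np.full((6, 6), 1.9)
        d[:3, :3] = 0.1
        d[3:, 3:] = 0.1
        np.fill_diagonal(d, 0.0)
        res = permanova(d, [0, 0, 0, 1, 1, 1], n_perm=999)
        assert res.exhaustive and res.n_perm == 20
        assert res.p_value == pytest.approx(2 / 20)

    def test_equal_distances_give_p_one(self):
        d = np.full((6, 6), 1.0)
        np.fill_diagonal(d, 0.0)
        res = permanova(d, [0, 0, 0, 1, 1, 1], n_perm=999)
        assert res.p_value == 1.0

    def test_all_zero_distances_f_zero(self):
        d = np.zeros((5, 5))
        res = permanova(d, [0, 0, 1, 1, 1], n_perm=99)
        assert res.pseudo_F == 0.0 and res.p_value == 1.0

    def test_monte_carlo_p_floor_and_determinism(self):
        rng = np.random.default_rng(7)
        N = 14
        d = np.zeros((N, N))
        iu = np.triu_indices(N, 1)
        d[iu] = rng.uniform(0.5, 1.5, len(iu[0]))
        d = d + d.T
        labels = np.array([0] * 7 + [1] * 7)
        r1 = permanova(d, labels, n_perm=199, seed=3)
        r2 = permanova(d, labels, n_perm=199, seed=3)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1 / 200

    def test_single_group_rejected(self):
        d = np.zeros((4, 4))
        with pytest.raises(ValueError, match="two"):
            permanova(d, [0, 0, 0, 0], n_perm=99)


class TestPartitionGuilds:
    def test_two_clade_worked_example(self):
        # A-vs-B significant; sub-splits homogeneous: exactly 2 guilds,
        # one recorded split and two stops
        dm, clades = planted_two_clade_distance(seed=0)
        tree = ward_tree(dm)
        part = partition_guilds(tree, dm, seed=1)
        assert part.n_guilds == 2
        recovered = {frozenset(part.members(g)) for g in part.guild_ids}
        assert recovered == {frozenset(clades["A"]), frozenset(clades["B"])}
        decisions = [t.decision for t in part.trail]
        assert decisions == ["split", "stop", "stop"]

    def test_alpha_zero_yields_one_guild(self):
        dm, _ = planted_two_clade_distance(seed=0)
        tree = ward_tree(dm)
        part = partition_guilds(tree, dm, alpha=0.0, seed=1)
        assert part.n_guilds == 1
        assert set(part.assignments.values()) == {"guild_1"}

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(8)
        n = 20
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        d[iu] = rng.uniform(0.1, 1.9, len(iu[0]))
        d = d + d.T
        dm = dist_from(d)
        tree = ward_tree(dm)
        counts = [
            partition_guilds(tree, dm, alpha=a, seed=5).n_guilds
            for a in (0.2, 0.1, 0.05, 0.01, 0.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_determinism_with_seed(self):
        dm, _ = planted_two_clade_distance(seed=3)
        tree = ward_tree(dm)
        p1 = partition_guilds(tree, dm, seed=11)
        p2 = partition_guilds(tree, dm, seed=11)
        assert p1 == p2

    def test_trail_reconstructs_partition(self):
        dm, _ = planted_two_clade_distance(seed=0)
        tree = ward_tree(dm)
        part = partition_guilds(tree, dm, seed=1)
        split_nodes = {t.node_id for t in part.trail if t.decision == "split"}

        def replay(node):
            if node < tree.n_leaves or node not in split_nodes:
                return [frozenset(tree.members(node))]
            left, right = tree.children(node)
            return replay(left) + replay(right)

        replayed = set(replay(tree.root))
        recovered = {
            frozenset(tree.feature_ids.index(f) for f in part.members(g))
            for g in part.guild_ids
        }
        assert replayed == recovered


class TestGuildAbundance:
    def test_members_summed(self):
        ft = FeatureTable(
            pd.DataFrame(
                [[2.0, 3.0], [1.0, 0.0]], index=["A", "B"], columns=["s1", "s2"]
            )
        )
        part = GuildPartition(assignments={"A": "guild_1", "B": "guild_1"})
        gt = guild_abundance(ft, part)
        np.testing.assert_array_equal(gt.values[0], [3.0, 3.0])

    def test_singleton_guild_equals_feature_row(self, tiny_ft):
        part = GuildPartition(
            assignments={"fA": "guild_1", "fB": "guild_2", "fC": "guild_2"}
        )
        gt = guild_abundance(tiny_ft, part)
        np.testing.assert_array_equal(
            gt.data.loc["guild_1"].to_numpy(), tiny_ft.data.loc["fA"].to_numpy()
        )

    def test_per_sample_totals_conserved_exactly(self, rng):
        values = rng.integers(0, 100, size=(15, 9)).astype(float)
        ft = FeatureTable(
            pd.DataFrame(
                values,
                index=[f"f{i}" for i in range(15)],
                columns=[f"s{j}" for j in range(9)],
            )
        )
        part = GuildPartition(
            assignments={f"f{i}": f"guild_{1 + i % 4}" for i in range(15)}
        )
        gt = guild_abundance(ft, part)
        np.testing.assert_array_equal(
            gt.values.sum(axis=0), ft.values.sum(axis=0)
        )

    def test_mismatched_features_rejected(self, tiny_ft):
        part = GuildPartition(assignments={"fA": "g1", "fB": "g1"})
        with pytest.raises(ValueError, match="not covered"):
            guild_abundance(tiny_ft, part)
        part2 = GuildPartition(
            assignments={"fA": "g1", "fB": "g1", "fC": "g1", "fX": "g2"}
        )
        with pytest.raises(ValueError, match="absent"):
            guild_abundance(tiny_ft, part2)


class TestGuildPartitionerEstimator:
    def test_fit_transform_on_block_structured_data(self):
        rng = np.random.default_rng(9)
        n, per_block = 50, 6
        z1, z2 = rng.standard_normal(n), rng.standard_normal(n)
        X = np.column_stack(
            [z1 + 0.2 * rng.standard_normal(n) for _ in range(per_block)]
            + [z2 + 0.2 * rng.standard_normal(n) for _ in range(per_block)]
        )
        est = GuildPartitioner(correlation="spearman", random_state=0)
        labels = est.fit_predict(X)
        assert est.n_guilds_ == 2
        assert len(set(labels[:per_block])) == 1
        assert len(set(labels[per_block:])) == 1
        G = est.transform(X)
        assert G.shape == (n, 2)
        np.testing.assert_allclose(G.sum(axis=1), X.sum(axis=1))

    def test_precomputed_correlation_input(self):
        r = np.eye(4)
        r[0, 1] = r[1, 0] = 0.9
        r[2, 3] = r[3, 2] = 0.9
        est = GuildPartitioner(correlation="precomputed", random_state=1)
        est.fit(r)
        assert est.labels_[0] == est.labels_[1]
        assert est.labels_[2] == est.labels_[3]

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = GuildPartitioner(alpha=0.01, n_perm=99, random_state=3)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
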