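"""Planted-guild generator: determinism, regimes, recovery metrics."""

import numpy as np
import pytest

from guildflow.guilds import GuildPartition
from guildflow.correlation import spearman_matrix
from guildflow.preprocess import sparsity
from guildflow.synthetic import (
    SimulationParams,
    evaluate_partition,
    simulate_cancellation,
    simulate_guild_data,
    simulate_phenotypes,
)
from guildflow.association import associate, classify_guilds
from guildflow.guilds import corr_to_dist, guild_abundance, partition_guilds, ward_tree


def within_between_medians(ft, truth):
    r = spearman_matrix(ft).r
    labels = np.array([truth.feature_guilds[f] for f in ft.feature_ids])
    within, between = [], []
    for g in np.unique(labels):
        if g == "none":
            continue
        idx = np.flatnonzero(labels == g)
        other = np.flatnonzero((labels != g) & (labels != "none"))
        sub = r[np.ix_(idx, idx)]
        within.extend(sub[np.triu_indices_from(sub, 1)])
        between.extend(np.abs(r[np.ix_(idx, other)]).ravel())
    return float(np.median(within)), float(np.median(between))


class TestGenerator:
    def test_fixed_seed_bit_identical(self):
        ft1, t1 = simulate_guild_data(seed=9)
        ft2, t2 = simulate_guild_data(seed=9)
        np.testing.assert_array_equal(ft1.values, ft2.values)
        assert t1.feature_guilds == t2.feature_guilds

    def test_default_regime_correlation_structure(self):
        # strong within-guild co-abundance, weak between-guild coupling
        within, between = [], []
        for seed in range(4):
            ft, truth = simulate_guild_data(seed=seed)
            w, b = within_between_medians(ft, truth)
            within.append(w)
            between.append(b)
        assert np.mean(within) >= 0.7
        assert np.mean(between) <= 0.15

    def test_no_dropout_high_depth_dense(self):
        params = SimulationParams(dropout_prob=0.0, sequencing_depth=10_000_000)
        ft, _ = simulate_guild_data(params, seed=1)
        assert sparsity(ft) < 0.01

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(dropout_prob=1.5).validate()
        with pytest.raises(ValueError):
            SimulationParams(sequencing_depth=10).validate()
        with pytest.raises(ValueError):
            SimulationParams(phenotype_effects=((7, 1.0, 0.1),)).validate()

    def test_loading_monotonically_strengthens_coabundance(self):
        means = []
        for lam in (0.25, 1.0, 3.0):
            vals = []
            for seed in range(4):
                params = SimulationParams(within_guild_loading=lam)
                ft, truth = simulate_guild_data(params, seed=seed)
                vals.append(within_between_medians(ft, truth)[0])
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]


class TestPhenotypes:
    def test_positive_effect_marks_guild_positive(self):
        params = SimulationParams(phenotype_effects=((0, 2.0, 0.1),))
        ft, truth = simulate_guild_data(params, seed=2)
        md = simulate_phenotypes(truth, params=params, seed=3)
        gt_true = truth.guild_relative_abundance
        from guildflow.containers import FeatureTable

        gt = FeatureTable(gt_true)
        at = associate(gt, md)
        cat = classify_guilds(at)
        assert cat["guild_1"] == "positive"

    def test_null_effects_rarely_significant(self):
        hits = 0
        n_runs = 30
        from guildflow.containers import FeatureTable

        params = SimulationParams(phenotype_effects=((0, 0.0, 1.0),))
        for k in range(n_runs):
            ft, truth = simulate_guild_data(params, seed=200 + k)
            md = simulate_phenotypes(truth, params=params, seed=900 + k)
            at = associate(FeatureTable(truth.guild_relative_abundance), md)
            hits += bool((at.q_value < 0.05).any())
        assert hits <= 0.1 * n_runs

    def test_opposite_signs_on_same_guild_yield_mixed(self):
        params = SimulationParams(
            phenotype_effects=((0, 2.0, 0.05), (0, -2.0, 0.05))
        )
        ft, truth = simulate_guild_data(params, seed=4)
        md = simulate_phenotypes(truth, params=params, seed=5)
        from guildflow.containers import FeatureTable

        at = associate(FeatureTable(truth.guild_relative_abundance), md)
        cat = classify_guilds(at)
        assert cat["guild_1"] == "mixed"


class TestCancellationFixture:
    def test_summed_trajectory_has_lower_variance(self):
        ft, tax, md, truth = simulate_cancellation(seed=0)
        rel = ft.data / ft.data.sum(axis=0)
        s1 = rel.loc["EE_strain_1"].to_numpy()
        s2 = rel.loc["EE_strain_2"].to_numpy()
        assert np.var(s1 + s2) < min(np.var(s1), np.var(s2))

    def test_zero_effect_mostly_silent(self):
        from guildflow.containers import FeatureTable

        hits = 0
        n_runs = 20
        for k in range(n_runs):
            ft, tax, md, truth = simulate_cancellation(effect=0.0, seed=300 + k)
            gt = FeatureTable(truth.guild_relative_abundance)
            at = associate(gt, md)
            hits += bool((at.q_value < 0.05).any())
        assert hits <= 0.1 * n_runs + 1

    def test_strains_share_species_label(self):
        _, tax, _, _ = simulate_cancellation(seed=1)
        assert tax.rank_of("EE_strain_1", "species") == "Eubacterium_eligens"
        assert tax.rank_of("EE_strain_2", "species") == "Eubacterium_eligens"


class TestEvaluatePartition:
    def truth_of(self, labels):
        from guildflow.synthetic import SyntheticTruth
        import pandas as pd

        return SyntheticTruth(
            feature_guilds=labels,
            latent=pd.DataFrame(),
            guild_relative_abundance=pd.DataFrame(),
            phenotype_effects=(),
            seed=0,
        )

    def test_identical_partition_scores_one(self):
        labels = {f"f{i}": f"guild_{1 + i // 4}" for i in range(20)}
        truth = self.truth_of(labels)
        part = GuildPartition(assignments=dict(labels))
        metrics = evaluate_partition(part, truth)
        assert metrics["ari"] == 1.0
        assert metrics["purity"] == 1.0
        assert metrics["guild_count_error"] == 0

    def test_random_assignment_near_zero_ari(self):
        rng = np.random.default_rng(0)
        labels = {f"f{i}": f"guild_{1 + i // 8}" for i in range(40)}
        truth = self.truth_of(labels)
        aris = []
        for _ in range(100):
            perm = rng.permutation(40)
            part = GuildPartition(
                assignments={
                    f"f{i}": f"guild_{1 + perm[i] // 8}" for i in range(40)
                }
            )
            aris.append(evaluate_partition(part, truth)["ari"])
        assert abs(np.mean(aris)) < 0.05

    def test_single_cluster_purity_is_one_fifth(self):
        labels = {f"f{i}": f"guild_{1 + i // 8}" for i in range(40)}
        truth = self.truth_of(labels)
        part = GuildPartition(assignments={f"f{i}": "guild_1" for i in range(40)})
        metrics = evaluate_partition(part, truth)
        assert metrics["purity"] == pytest.approx(1 / 5)

    def test_disjoint_feature_sets_rejected(self):
        truth = self.truth_of({"a": "guild_1"})
        part = GuildPartition(assignments={"b": "guild_1"})
        with pytest.raises(ValueError, match="share no features"):
            evaluate_partition(part, truth)


class TestEndToEndRecovery:
    def test_default_settings_recover_planted_guilds(self):
        # spearman path on a few seeds (the bootstrap path at full scale is
        # exercised by the acceptance suite)
        aris = []
        for seed in range(3):
            ft, truth = simulate_guild_data(seed=seed)
            from guildflow.preprocess import prevalence_filter

            ft_f, _ = prevalence_filter(ft, 0.2)
            cm = spearman_matrix(ft_f)
            dm = corr_to_dist(cm)
            part = partition_guilds(ward_tree(dm), dm, seed=seed)
            aris.append(evaluate_partition(part, truth)["ari"])
        assert np.mean(aris) >= 0.8
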