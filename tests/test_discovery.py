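"""Discovery algorithms: planted-block recovery, degenerate cases, registry."""

import numpy as np
import pytest

from sabre import (
    DiscoveryConfig,
    ExpressionMatrix,
    GeneModule,
    ModuleSet,
    PlantedDesign,
    best_match,
    choose_k_elbow,
    discover,
    discover_kmeans_chaussabel,
    discover_wgcna_like,
    generate_null,
    generate_planted,
    pick_soft_power,
    register_algorithm,
)
from sabre.discovery import _kmeans_best_of, explained_variance_path, scale_free_fit


class TestWgcnaLike:
    def test_recovers_planted_blocks(self, planted, default_config):
        x, truth = planted
        ms = discover_wgcna_like(x, default_config)
        for m in truth.modules:
            score, _ = best_match(m, ms, "min_overlap")
            assert score >= 0.95

    def test_degenerate_cut_yields_single_module(self, planted_x):
        cfg = DiscoveryConfig(soft_power=1, cut_height=1.0)
        ms = discover_wgcna_like(planted_x, cfg)
        assert len(ms) == 1
        assert ms.modules[0].size == planted_x.n_features

    @pytest.mark.parametrize("seed", range(20))
    def test_noise_mostly_unassigned(self, seed, default_config):
        x = generate_null(200, 100, seed=seed)
        ms = discover_wgcna_like(x, default_config)
        assert len(ms.unassigned) / 200 > 0.5

    def test_zero_variance_feature_goes_to_unassigned(self, planted_x, default_config):
        values = np.vstack([planted_x.values, np.zeros(planted_x.n_samples)])
        x = ExpressionMatrix(planted_x.feature_ids + ("flat",), planted_x.sample_ids, values)
        ms = discover_wgcna_like(x, default_config)
        assert "flat" in ms.unassigned

    def test_too_few_samples_is_an_error(self, default_config):
        x = generate_null(30, 3, seed=0)
        with pytest.raises(ValueError, match="samples"):
            discover_wgcna_like(x, default_config)

    def test_membership_invariant_to_feature_permutation(self, planted_x, default_config, rng):
        perm = rng.permutation(planted_x.n_features)
        xp = ExpressionMatrix(
            tuple(planted_x.feature_ids[i] for i in perm),
            planted_x.sample_ids,
            planted_x.values[perm],
        )
        a = discover_wgcna_like(planted_x, default_config)
        b = discover_wgcna_like(xp, default_config)
        assert {m.members for m in a.modules} == {m.members for m in b.modules}

    def test_module_set_invariants_hold(self, planted_x, default_config):
        ms = discover_wgcna_like(planted_x, default_config)
        assert ms.universe == set(planted_x.feature_ids)
        assert all(m.size >= default_config.min_module_size for m in ms.modules)


class TestSoftPower:
    def test_threshold_zero_returns_smallest(self, planted_x):
        assert pick_soft_power(planted_x, [2, 4, 6], target_r2=0.0) == 2

    def test_single_candidate_forced(self, planted_x):
        assert pick_soft_power(planted_x, [6], target_r2=0.99) == 6

    def test_returned_power_consistent_with_oracle_fits(self, planted_x):
        from sabre.discovery import _row_correlation

        candidates = list(range(1, 13))
        target = 0.8
        chosen = pick_soft_power(planted_x, candidates, target_r2=target)
        cor = np.abs(_row_correlation(planted_x.values))
        np.fill_diagonal(cor, 0.0)
        fits = {b: scale_free_fit((cor**b).sum(axis=1)) for b in candidates}
        reaching = [b for b in candidates if fits[b] >= target]
        if reaching:
            assert chosen == min(reaching)
        else:
            assert chosen == max(fits, key=fits.get)

    def test_degenerate_connectivity_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            scale_free_fit(np.full(50, 3.0))


class TestKmeans:
    def test_two_separated_blocks_exact_partition(self):
        x, truth = generate_planted(PlantedDesign(module_sizes=(60, 60), n_background=0, seed=3))
        ms = discover_kmeans_chaussabel(x, DiscoveryConfig(k=2))
        assert {m.members for m in ms.modules} == {m.members for m in truth.modules}
        assert not ms.unassigned

    def test_k_equals_feature_count_gives_zero_wss(self):
        x = generate_null(12, 8, seed=0)
        ms = discover_kmeans_chaussabel(x, DiscoveryConfig(k=12, n_starts=2))
        assert len(ms) == 12
        assert ms.provenance["wss"] == pytest.approx(0.0, abs=1e-9)

    def test_k_larger_than_feature_count_is_an_error(self):
        x = generate_null(5, 8, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            discover_kmeans_chaussabel(x, DiscoveryConfig(k=9))

    def test_same_seed_reproduces_module_set(self, planted_x):
        cfg = DiscoveryConfig(k=4, seed=7)
        a = discover_kmeans_chaussabel(planted_x, cfg)
        b = discover_kmeans_chaussabel(planted_x, cfg)
        assert [m.members for m in a.modules] == [m.members for m in b.modules]

    def test_retained_wss_is_minimum_over_starts(self, planted_x):
        ms = discover_kmeans_chaussabel(planted_x, DiscoveryConfig(k=5, n_starts=6, seed=1))
        assert ms.provenance["wss"] == pytest.approx(min(ms.provenance["all_start_wss"]))
        assert len(ms.provenance["all_start_wss"]) == 6

    def test_membership_invariant_to_feature_permutation(self, rng):
        x, _ = generate_planted(PlantedDesign(module_sizes=(40, 40, 40), n_background=0, seed=5))
        perm = rng.permutation(x.n_features)
        xp = ExpressionMatrix(tuple(x.feature_ids[i] for i in perm), x.sample_ids, x.values[perm])
        a = discover_kmeans_chaussabel(x, DiscoveryConfig(k=3, seed=2))
        b = discover_kmeans_chaussabel(xp, DiscoveryConfig(k=3, seed=2))
        assert {m.members for m in a.modules} == {m.members for m in b.modules}


class TestElbow:
    def test_four_separated_blocks(self):
        x, _ = generate_planted(PlantedDesign(module_sizes=(40, 40, 40, 40), n_background=0, seed=2))
        votes = [choose_k_elbow(x, list(range(2, 11)), seed=s, n_starts=4) for s in range(10)]
        k = int(np.median(votes))
        assert abs(k - 4) <= 1

    def test_matches_independent_gain_sequence_on_noise(self):
        x = generate_null(40, 10, seed=4)
        ks = list(range(2, 9))
        chosen = choose_k_elbow(x, ks, seed=0, threshold=0.01, n_starts=3)
        path = explained_variance_path(x, [1] + ks, seed=0, n_starts=3)
        gains = [path[i + 1] - path[i] for i in range(len(ks))]
        below = [k for k, g in zip(ks, gains) if g < 0.01]
        assert chosen == (below[0] if below else ks[-1])

    def test_huge_threshold_stops_immediately(self, planted_x):
        assert choose_k_elbow(planted_x, [2, 3, 4], seed=0, threshold=1.0, n_starts=2) == 2

    def test_k_range_validation(self, planted_x):
        with pytest.raises(ValueError):
            choose_k_elbow(planted_x, [2, 3], seed=0)


class TestRegistry:
    def test_register_and_dispatch(self, planted_x):
        def one_module(x, cfg):
            return ModuleSet((GeneModule("ALL", frozenset(x.feature_ids)),))

        register_algorithm("one_module_test", one_module)
        cfg = DiscoveryConfig(algorithm="one_module_test")
        ms = discover(planted_x, cfg)
        assert len(ms) == 1 and ms.modules[0].size == planted_x.n_features
        with pytest.raises(ValueError, match="already registered"):
            register_algorithm("one_module_test", one_module)

    def test_unknown_algorithm_is_an_error(self, planted_x):
        with pytest.raises(KeyError, match="unknown"):
            discover(planted_x, DiscoveryConfig(algorithm="nope"))
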