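"""Fisher enrichment against exact rational oracles, permutation behaviour,
and the empirical null-threshold calibration."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from mirenrich import (
    SimulationConfig,
    TargetPredictionTable,
    calibrate_null_threshold,
    enrich_gene_list,
    filter_by_calibration,
    fisher_enrichment,
    generate_null_study,
    permute_predictions,
)
from mirenrich.enrichment import (
    NullCalibration,
    hypergeom_upper_tail,
    nearest_rank_quantile,
)


def exact_upper_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact rational P(X >= k) for the hypergeometric 2x2 table."""
    total = comb(N, n)
    return Fraction(
        sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)),
        total,
    )


class TestFisherEnrichment:
    def test_full_overlap_small_table(self):
        # N=20, K=10, n=5, k=5 -> C(10,5)/C(20,5) = 252/15504
        universe = [f"g{i}" for i in range(20)]
        record = fisher_enrichment(universe[:5], universe[:10], universe)
        assert record.k == 5 and record.n == 5 and record.K == 10 and record.N == 20
        assert record.p_nominal == pytest.approx(252 / 15504, abs=1e-12)

    def test_empty_list_gives_p_one_and_zero_odds(self):
        universe = ["g1", "g2", "g3"]
        record = fisher_enrichment([], ["g1"], universe)
        assert record.p_nominal == 1.0
        assert record.odds_ratio == 0.0

    def test_minimum_possible_overlap_gives_p_one(self):
        # n + K - N forces the overlap; upper tail then covers full support
        universe = [f"g{i}" for i in range(10)]
        record = fisher_enrichment(universe[:6], universe[4:], universe)
        assert record.k == 2  # max(0, 6 + 6 - 10)
        assert record.p_nominal == pytest.approx(1.0, abs=1e-12)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_enrichment(["g1"], ["g1"], [])

    def test_matches_exact_rational_oracle_on_small_universes(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    lo = max(0, n + K - N)
                    for k in range(lo, min(K, n) + 1):
                        got = float(hypergeom_upper_tail(k, N, K, n))
                        want = float(exact_upper_tail(k, N, K, n))
                        assert got == pytest.approx(want, abs=1e-12)

    def test_p_strictly_decreasing_in_overlap(self):
        N, K, n = 100, 20, 30
        tails = [float(hypergeom_upper_tail(k, N, K, n)) for k in range(0, 21)]
        assert all(a > b for a, b in zip(tails, tails[1:]))

    def test_genes_outside_universe_are_dropped(self):
        universe = ["g1", "g2", "g3", "g4"]
        record = fisher_enrichment(
            ["g1", "gX"], ["g1", "gY"], universe
        )
        assert record.n == 1 and record.K == 1 and record.k == 1


class TestEnrichGeneList:
    def test_only_expressed_mirnas_get_records(self, small_study):
        records = enrich_gene_list(
            list(small_study.expression.gene_ids[:50]),
            small_study.predictions,
            small_study.expression.gene_ids,
            {"miR-001"},
        )
        assert {r.mirna for r in records} == {"miR-001"}

    def test_single_mirna_adjusted_equals_nominal(self, small_study):
        records = enrich_gene_list(
            list(small_study.expression.gene_ids[:50]),
            small_study.predictions,
            small_study.expression.gene_ids,
            {"miR-001"},
        )
        for record in records:
            assert record.p_adjusted == record.p_nominal

    def test_disjoint_expressed_set_is_an_error(self, small_study):
        with pytest.raises(ValueError, match="expressed"):
            enrich_gene_list(
                list(small_study.expression.gene_ids[:50]),
                small_study.predictions,
                small_study.expression.gene_ids,
                {"miR-does-not-exist"},
            )

    def test_planted_mirnas_attain_smallest_adjusted_p(self):
        hits = 0
        runs = 10
        for seed in range(runs):
            config = SimulationConfig(
                n_genes=1000, n_samples_pos=20, n_samples_neg=20, n_mirnas=20,
                n_planted=3, regulon_size=30, effect_size=2.0, seed=seed,
            )
            from mirenrich import derive_de_lists, generate_study

            study = generate_study(config)
            lists = derive_de_lists(study.expression, study.labels)
            records = enrich_gene_list(
                lists.down,
                study.predictions,
                study.expression.gene_ids,
                study.expressed_mirnas,
            )
            ok = True
            for algorithm in study.predictions.algorithms:
                family = [r for r in records if r.algorithm == algorithm]
                family.sort(key=lambda r: r.p_adjusted)
                top = {r.mirna for r in family[: len(study.planted_mirnas)]}
                ok &= top == study.planted_mirnas
            hits += ok
        assert hits >= 0.9 * runs


class TestPermutePredictions:
    def test_sizes_and_roster_preserved(self, small_study):
        rng = np.random.default_rng(0)
        universe = frozenset(small_study.expression.gene_ids)
        permuted = permute_predictions(small_study.predictions, universe, rng)
        assert permuted.algorithms == small_study.predictions.algorithms
        assert set(permuted.sets) == set(small_study.predictions.sets)
        for key, genes in small_study.predictions.sets.items():
            assert len(permuted.sets[key]) == len(genes)

    def test_empty_set_stays_empty(self):
        table = TargetPredictionTable(
            ("A", "B"), {("A", "m1"): frozenset(), ("B", "m1"): frozenset({"g1"})}
        )
        permuted = permute_predictions(table, {"g1", "g2"}, np.random.default_rng(0))
        assert permuted.get("A", "m1") == frozenset()

    def test_set_larger_than_universe_is_an_error(self):
        table = TargetPredictionTable(("A", "B"), {("A", "m1"): frozenset({"g1", "g2"})})
        with pytest.raises(ValueError, match="universe"):
            permute_predictions(table, {"g1"}, np.random.default_rng(0))

    def test_uniform_inclusion_frequency(self):
        # every universe gene should enter a size-10 random set with
        # frequency 10/N across many permutations
        N = 40
        universe = frozenset(f"g{i}" for i in range(N))
        table = TargetPredictionTable(
            ("A", "B"),
            {("A", "m1"): frozenset(list(universe)[:10])},
            explicit_universe={"A": universe, "B": universe},
        )
        rng = np.random.default_rng(1)
        counts = {g: 0 for g in universe}
        n_perm = 1000
        for _ in range(n_perm):
            for g in permute_predictions(table, universe, rng).get("A", "m1"):
                counts[g] += 1
        freq = np.array(list(counts.values())) / n_perm
        p = 10 / N
        se = np.sqrt(p * (1 - p) / n_perm)
        assert np.all(np.abs(freq - p) < 5 * se)


class TestCalibration:
    def test_nearest_rank_quantile_is_tenth_smallest_of_thousand(self):
        rng = np.random.default_rng(2)
        pool = rng.uniform(size=1000)
        want = np.sort(pool)[9]
        assert nearest_rank_quantile(pool, 0.01) == want

    def test_quantile_of_identical_values_is_that_value(self):
        assert nearest_rank_quantile([0.4] * 50, 0.01) == 0.4

    def test_threshold_at_boundary_is_inclusive(self):
        universe = [f"g{i}" for i in range(30)]
        record = fisher_enrichment(
            universe[:5], universe[:10], universe, algorithm="A",
            list_id=("d", "down"),
        )
        from dataclasses import replace

        record = replace(record, p_adjusted=record.p_nominal)
        calibration = NullCalibration(
            algorithm="A",
            list_id=("d", "down"),
            n_permutations=10,
            null_quantile=0.01,
            threshold_nominal=record.p_nominal,
            threshold_adjusted=record.p_nominal,
            seed=0,
        )
        (out,) = filter_by_calibration([record], {"A": calibration})
        assert out.passes_calibration is True
        assert calibration.max_retained_nominal == record.p_nominal

    def test_nothing_passes_when_threshold_below_all(self):
        universe = [f"g{i}" for i in range(30)]
        record = fisher_enrichment(
            universe[:5], universe[10:20], universe, algorithm="A",
            list_id=("d", "down"),
        )
        calibration = NullCalibration(
            algorithm="A",
            list_id=("d", "down"),
            n_permutations=10,
            null_quantile=0.01,
            threshold_nominal=0.0,
            threshold_adjusted=0.0,
            seed=0,
        )
        (out,) = filter_by_calibration([record], {"A": calibration})
        assert out.passes_calibration is False
        assert calibration.max_retained_nominal == 0.0

    def test_mismatched_calibration_key_is_an_error(self):
        universe = [f"g{i}" for i in range(30)]
        record = fisher_enrichment(
            universe[:5], universe[:10], universe, algorithm="A",
            list_id=("d", "down"),
        )
        calibration = NullCalibration(
            algorithm="A",
            list_id=("other", "up"),
            n_permutations=10,
            null_quantile=0.01,
            threshold_nominal=0.5,
            threshold_adjusted=0.5,
            seed=0,
        )
        with pytest.raises(ValueError, match="no calibration"):
            filter_by_calibration([record], {"A": calibration})

    def test_deterministic_given_seed(self):
        config = SimulationConfig(
            n_genes=200, n_samples_pos=5, n_samples_neg=5, n_mirnas=8,
            regulon_size=15, seed=4,
        )
        study = generate_null_study(config)
        genes = study.expression.gene_ids
        args = (
            frozenset(genes[:40]),
            study.predictions,
            frozenset(genes),
            study.expressed_mirnas,
        )
        c1 = calibrate_null_threshold(*args, n_perm=20, seed=99)
        c2 = calibrate_null_threshold(*args, n_perm=20, seed=99)
        for algorithm in c1:
            assert c1[algorithm].threshold_nominal == c2[algorithm].threshold_nominal
            assert c1[algorithm].threshold_adjusted == c2[algorithm].threshold_adjusted

    def test_resolution_limited_pool_warns(self, small_study):
        genes = small_study.expression.gene_ids
        with pytest.warns(UserWarning, match="resolve quantile"):
            calibrate_null_threshold(
                frozenset(genes[:30]),
                small_study.predictions,
                frozenset(genes),
                {"miR-001"},
                n_perm=1,
                null_quantile=0.01,
                seed=0,
            )
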