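"""Presence filtering, pooled-variance t-statistics, and the KS comparison of
target versus non-target t distributions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_dataset, make_labels
from mirenrich import (
    PresenceRule,
    SimulationConfig,
    TargetPredictionTable,
    gene_t_statistics,
    generate_study,
    ks_target_enrichment,
    ks_two_sample,
    presence_filter,
)


def ecdf_sup_oracle(x, y) -> float:
    """Brute-force sup over the pooled grid of |ECDF_x - ECDF_y|."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    best = 0.0
    for v in np.concatenate([x, y]):
        fx = np.mean(x <= v)
        fy = np.mean(y <= v)
        best = max(best, abs(fx - fy))
    return best


class TestPresenceFilter:
    def _dataset(self, present_counts, n_samples=10):
        # genes expressed high in the first `count` samples, low elsewhere;
        # background genes make the low value sit below the quantile
        rows = []
        for count in present_counts:
            rows.append([10.0] * count + [0.0] * (n_samples - count))
        rows.append([10.0] * n_samples)  # anchor so the quantile is defined
        rows.append([0.0] * n_samples)
        return make_dataset(rows)

    def test_exactly_sixty_percent_is_retained(self):
        ds = self._dataset([6, 5])
        retained = presence_filter(ds, PresenceRule(quantile=0.25, min_fraction=0.6))
        assert "g0" in retained  # 6/10 samples
        assert "g1" not in retained  # 5/10 samples

    def test_raising_min_fraction_never_adds_genes(self):
        ds = self._dataset([3, 5, 6, 8, 10])
        previous = None
        for fraction in (0.2, 0.4, 0.6, 0.8, 1.0):
            retained = presence_filter(
                ds, PresenceRule(quantile=0.25, min_fraction=fraction)
            )
            if previous is not None:
                assert retained <= previous
            previous = retained

    def test_constant_dataset_fails_explicitly(self):
        ds = make_dataset(np.full((4, 6), 3.0))
        with pytest.raises(ValueError, match="retained no genes"):
            presence_filter(ds, PresenceRule())

    def test_external_calls_mode(self):
        ds = make_dataset(np.zeros((2, 4)) + np.arange(4))
        calls = pd.DataFrame(
            [[1, 1, 1, 0], [1, 0, 0, 0]], index=["g0", "g1"],
            columns=["s0", "s1", "s2", "s3"],
        )
        rule = PresenceRule(mode="external_calls", min_fraction=0.6, calls=calls)
        assert presence_filter(ds, rule) == {"g0"}

    def test_external_calls_shape_mismatch_fails(self):
        ds = make_dataset(np.zeros((2, 4)) + np.arange(4))
        calls = pd.DataFrame([[1, 1]], index=["g0"], columns=["s0", "s1"])
        rule = PresenceRule(mode="external_calls", calls=calls)
        with pytest.raises(ValueError, match="does not match"):
            presence_filter(ds, rule)


class TestGeneTStatistics:
    def test_hand_worked_pooled_t(self):
        # means 2 vs 5, pooled sd 1, se = sqrt(2/3) -> t = -3/0.8165
        ds = make_dataset([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        labels = make_labels(["s0", "s1", "s2"], ["s3", "s4", "s5"])
        tstats = gene_t_statistics(ds, labels, ["g0"])
        assert tstats.t["g0"] == pytest.approx(-3 / np.sqrt(2 / 3), abs=1e-9)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(rng.normal(size=(20, 12)))
        labels = make_labels([f"s{j}" for j in range(6)], [f"s{j}" for j in range(6, 12)])
        tstats = gene_t_statistics(ds, labels, ds.gene_ids)
        ref = stats.ttest_ind(ds.values[:, :6], ds.values[:, 6:], axis=1)
        for gene, t_ref in zip(ds.gene_ids, ref.statistic):
            assert tstats.t[gene] == pytest.approx(t_ref, abs=1e-10)

    def test_sign_flips_when_labels_swap(self):
        rng = np.random.default_rng(4)
        ds = make_dataset(rng.normal(size=(5, 8)))
        pos, neg = [f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 8)]
        forward = gene_t_statistics(ds, make_labels(pos, neg), ds.gene_ids)
        backward = gene_t_statistics(ds, make_labels(neg, pos), ds.gene_ids)
        for gene in ds.gene_ids:
            assert forward.t[gene] == pytest.approx(-backward.t[gene], abs=1e-12)

    def test_zero_variance_genes_dropped(self):
        ds = make_dataset([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        labels = make_labels(["s0", "s1"], ["s2", "s3"])
        tstats = gene_t_statistics(ds, labels, ds.gene_ids)
        assert "g0" not in tstats.t
        assert "g1" in tstats.t


class TestKsTwoSample:
    def test_interleaved_pair(self):
        d, _ = ks_two_sample([1.0, 2.0], [0.0, 3.0])
        assert d == 0.5

    def test_identical_samples_give_zero(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_supports_give_one(self):
        d, _ = ks_two_sample([1.0, 2.0], [5.0, 6.0])
        assert d == 1.0

    def test_statistic_matches_pooled_grid_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            x = rng.integers(0, 7, size=rng.integers(1, 13)).astype(float)
            y = rng.integers(0, 7, size=rng.integers(1, 13)).astype(float)
            d, _ = ks_two_sample(x, y)
            assert d == ecdf_sup_oracle(x, y)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            ks_two_sample([], [1.0])


class TestKsTargetEnrichment:
    def _study(self, seed=31):
        # default study conditions: effect 1 SD; much larger effects push
        # repressed targets below the presence threshold in R+ samples and
        # the filter drops them before the KS stage sees anything
        return generate_study(SimulationConfig(n_mirnas=20, n_planted=3, seed=seed))

    def _tstats(self, study):
        retained = presence_filter(study.expression, PresenceRule())
        return gene_t_statistics(study.expression, study.labels, retained)

    def test_planted_mirnas_significant_under_multiple_algorithms(self):
        study = self._study()
        records = ks_target_enrichment(
            self._tstats(study), study.predictions, study.expressed_mirnas, "d1"
        )
        for mirna in study.planted_mirnas:
            n_support = sum(
                1 for r in records
                if r.mirna == mirna and r.significant and not r.skipped
            )
            assert n_support >= 2

    def test_null_study_flags_nearly_nothing(self):
        from mirenrich import generate_null_study

        study = generate_null_study(SimulationConfig(n_mirnas=20, seed=32))
        records = ks_target_enrichment(
            self._tstats(study), study.predictions, study.expressed_mirnas, "d1"
        )
        n_sig = sum(1 for r in records if r.significant)
        assert n_sig <= 2

    def test_sparse_target_overlap_yields_skipped_record(self):
        study = self._study()
        tstats = self._tstats(study)
        predictions = TargetPredictionTable(
            ("A", "B"),
            {
                ("A", "miR-001"): frozenset(list(tstats.retained)[:3]),
                ("B", "miR-001"): frozenset(list(tstats.retained)[:12]),
            },
        )
        records = ks_target_enrichment(
            tstats, predictions, {"miR-001"}, "d1", min_targets=10
        )
        by_alg = {r.algorithm: r for r in records}
        assert by_alg["A"].skipped is True
        assert by_alg["A"].significant is False
        assert by_alg["B"].skipped is False
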