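"""Unit and property tests for the bulk transcriptome stage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from cgsc import (
    bulk_deg,
    build_centroid,
    correlation_matrix,
    counts_to_tpm,
    embed_with_centroid,
    kappa_from_counts,
    ora_enrichment,
    pathway_agreement,
    size_factors,
)
from cgsc.bulk import GROUP_DC, GROUP_IC


def _groups(n=3):
    samples = [f"{GROUP_DC}{i}" for i in range(n)] + [f"{GROUP_IC}{i}" for i in range(n)]
    return pd.Series([GROUP_DC] * n + [GROUP_IC] * n, index=samples)


class TestTpm:
    def test_single_gene_takes_the_whole_million(self):
        counts = pd.DataFrame({"s1": [7]}, index=["g1"])
        tpm = counts_to_tpm(counts, pd.Series({"g1": 1234.0}))
        assert tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_hand_arithmetic(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["a", "b"])
        lengths = pd.Series({"a": 1000.0, "b": 2000.0})
        tpm = counts_to_tpm(counts, lengths)
        assert tpm.loc["a", "s"] == pytest.approx(666666.6667, rel=1e-6)
        assert tpm.loc["b", "s"] == pytest.approx(333333.3333, rel=1e-6)

    def test_equal_lengths_preserve_proportions(self, rng):
        counts = pd.DataFrame(rng.poisson(20, size=(10, 3)))
        lengths = pd.Series(1000.0, index=counts.index)
        tpm = counts_to_tpm(counts, lengths)
        for col in counts:
            expected = counts[col] / counts[col].sum() * 1e6
            assert np.allclose(tpm[col], expected)

    def test_columns_sum_to_a_million(self, small_bulk):
        tpm = counts_to_tpm(small_bulk.counts, small_bulk.gene_lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_all_zero_sample_named(self):
        counts = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            counts_to_tpm(counts, pd.Series({"a": 100.0, "b": 100.0}))


class TestSizeFactors:
    def test_identical_samples_are_unit(self):
        counts = pd.DataFrame({"s1": [5, 10, 3], "s2": [5, 10, 3], "s3": [5, 10, 3]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_sample_gets_double_factor(self):
        a = np.array([10, 20, 40, 7])
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        f = size_factors(counts)
        assert f["B"] / f["A"] == pytest.approx(2.0)

    def test_single_sample_factor_one(self):
        counts = pd.DataFrame({"only": [3, 1, 4]})
        assert size_factors(counts).tolist() == [1.0]

    def test_no_common_nonzero_gene_is_an_error(self):
        counts = pd.DataFrame({"s1": [1, 0], "s2": [0, 1]})
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(counts)


class TestBulkDeg:
    def test_identical_groups_yield_no_degs(self, rng):
        base = rng.poisson(100, size=(200, 3))
        counts = pd.DataFrame(np.hstack([base, base]), columns=_groups().index)
        table = bulk_deg(counts, _groups())
        assert table["is_deg"].sum() == 0

    def test_all_zero_gene_is_null(self, rng):
        values = rng.poisson(50, size=(5, 6))
        values[2] = 0
        counts = pd.DataFrame(values, columns=_groups().index)
        table = bulk_deg(counts, _groups())
        assert table.iloc[2]["p"] == 1.0
        assert table.iloc[2]["log2fc"] == 0.0

    def test_planted_recovery_without_false_positives(self, small_bulk):
        table = bulk_deg(small_bulk.counts, small_bulk.groups)
        truth = small_bulk.true_log2_effect != 0
        recall = (table["is_deg"] & truth).sum() / truth.sum()
        assert recall >= 0.8
        assert (table["is_deg"] & ~truth).sum() == 0
        # planted direction is recovered
        up = small_bulk.true_log2_effect > 0
        called_up = table["is_deg"] & (table["direction"] == "up")
        assert (called_up & ~up).sum() == 0

    def test_group_validation(self):
        counts = pd.DataFrame(np.ones((3, 4)), columns=["a", "b", "c", "d"])
        with pytest.raises(ValueError):
            bulk_deg(counts, pd.Series(["x", "x", "y", "y"], index=counts.columns))


class TestCorrelation:
    def test_unit_diagonal_and_symmetry(self, small_bulk):
        corr = correlation_matrix(small_bulk.counts)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_exact_linearity(self):
        expr = pd.DataFrame({"s1": [1.0, 2, 3], "s2": [2.0, 4, 6]})
        corr = correlation_matrix(expr, log_transform=False)
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)

    def test_constant_sample_missing_off_diagonal(self):
        expr = pd.DataFrame({"flat": [1.0, 1, 1], "vary": [1.0, 2, 3]})
        corr = correlation_matrix(expr, log_transform=False)
        assert np.isnan(corr.loc["flat", "vary"])
        assert corr.loc["flat", "flat"] == 1.0

    def test_within_group_exceeds_between_group(self, small_bulk):
        tpm = counts_to_tpm(small_bulk.counts, small_bulk.gene_lengths)
        corr = correlation_matrix(tpm)
        groups = small_bulk.groups
        same = groups.to_numpy()[:, None] == groups.to_numpy()[None, :]
        off_diag = ~np.eye(len(groups), dtype=bool)
        within = corr.to_numpy()[same & off_diag].mean()
        between = corr.to_numpy()[~same].mean()
        assert within > between


class TestCentroid:
    def test_single_cell_centroid_is_that_cell(self):
        m = pd.DataFrame({"c1": [1.0, 2], "c2": [5.0, 6]}, index=["g1", "g2"])
        centroid = build_centroid(m, np.array([True, False]), ["g1", "g2"])
        assert centroid.tolist() == [1.0, 2.0]

    def test_mean_of_two_cells(self):
        m = pd.DataFrame({"c1": [0.0], "c2": [2.0]}, index=["g1"])
        centroid = build_centroid(m, np.array([True, True]), ["g1"])
        assert centroid["g1"] == 1.0

    def test_empty_intersection_is_an_error(self):
        m = pd.DataFrame({"c1": [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="intersection"):
            build_centroid(m, np.array([True]), ["other"])

    def test_centroid_tracks_planted_cells(self, small_cohort):
        from cgsc import classify_osn, marker_thresholds, wilcoxon_deg

        m = small_cohort.counts
        labels = classify_osn(m, marker_thresholds(m))
        deg = wilcoxon_deg(m, labels["is_cgsc"])
        genes = deg.index[deg["is_deg"]]
        centroid = build_centroid(m, labels["is_cgsc"], genes)
        planted_mean = m.loc[genes, small_cohort.planted].mean(axis=1)
        background_mean = m.loc[genes, ~small_cohort.planted].mean(axis=1)
        joint = pd.concat(
            [planted_mean, background_mean, centroid], axis=1,
            keys=["planted", "background", "centroid"],
        )
        z = (joint - joint.mean(axis=1).to_numpy()[:, None]) / joint.std(axis=1).to_numpy()[:, None]
        d_planted = np.linalg.norm(z["centroid"] - z["planted"])
        d_background = np.linalg.norm(z["centroid"] - z["background"])
        assert d_planted < d_background


class TestEmbedding:
    def _inputs(self, small_bulk, small_cohort):
        from cgsc import classify_osn, marker_thresholds, wilcoxon_deg

        m = small_cohort.counts
        labels = classify_osn(m, marker_thresholds(m))
        deg = wilcoxon_deg(m, labels["is_cgsc"])
        genes = deg.index[deg["is_deg"]].intersection(small_bulk.counts.index)
        centroid = build_centroid(m, labels["is_cgsc"], genes)
        return small_bulk.counts.loc[genes], centroid

    def test_deterministic_under_fixed_seed(self, small_bulk, small_cohort):
        expr, centroid = self._inputs(small_bulk, small_cohort)
        a = embed_with_centroid(expr, centroid, seed=5)
        b = embed_with_centroid(expr, centroid, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_centroid_lands_near_icgsc_group(self, small_bulk, small_cohort):
        # the bulk ic-GSC group shares the planted stemness-up /
        # HLA-down signature with the c-GSC centroid
        expr, centroid = self._inputs(small_bulk, small_cohort)
        groups = small_bulk.groups
        successes = 0
        for seed in range(10):
            coords = embed_with_centroid(expr, centroid, seed=seed)
            center = coords.loc["centroid"]
            dists = {
                g: np.linalg.norm(
                    coords.loc[groups.index[groups == g]].mean(axis=0) - center
                )
                for g in (GROUP_DC, GROUP_IC)
            }
            successes += dists[GROUP_IC] < dists[GROUP_DC]
        assert successes >= 8

    def test_too_few_points_rejected(self):
        expr = pd.DataFrame({"s1": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match=">= 3 points"):
            embed_with_centroid(expr, pd.Series({"g1": 1.5, "g2": 0.5}))

    def test_oversized_perplexity_rejected_with_hint(self, small_bulk, small_cohort):
        expr, centroid = self._inputs(small_bulk, small_cohort)
        with pytest.raises(ValueError, match="use <="):
            embed_with_centroid(expr, centroid, perplexity=10)


class TestOra:
    def test_fisher_matches_hypergeometric_oracle(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = set(universe[:10])
        query = set(universe[5:15])  # overlap 5
        table = ora_enrichment(query, {"path": gene_set}, universe, min_set_size=1)
        # P(X >= 5), X ~ Hypergeom(N=100, K=10, n=10)
        expected = stats.hypergeom.sf(4, 100, 10, 10)
        assert table.loc["path", "p"] == pytest.approx(expected, rel=1e-9)
        assert table.loc["path", "overlap"] == 5

    def test_overlap_at_expectation_not_significant(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = set(universe[:10])
        query = set(universe[9:19])  # overlap 1 = expectation
        table = ora_enrichment(query, {"path": gene_set}, universe, min_set_size=1)
        assert table.loc["path", "p"] > 0.05

    def test_query_equals_universe_is_uninformative(self):
        universe = [f"g{i}" for i in range(20)]
        table = ora_enrichment(universe, {"all": set(universe)}, universe, min_set_size=1)
        assert table.loc["all", "p"] == pytest.approx(1.0)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="query"):
            ora_enrichment([], {"s": {"a"}}, ["a", "b"])


class TestAgreement:
    def _result(self, a, b, c, d):
        universe = [f"p{i}" for i in range(a + b + c + d)]
        set_a = set(universe[: a + b])
        set_b = set(universe[:a]) | set(universe[a + b : a + b + c])
        return pathway_agreement(set_a, set_b, universe)

    def test_hand_computed_case(self):
        res = self._result(5, 2, 3, 90)
        assert (res.a, res.b, res.c, res.d) == (5, 2, 3, 90)
        assert res.po == pytest.approx(0.95)
        assert res.pe == pytest.approx(0.8612)
        assert res.kappa == pytest.approx((0.95 - 0.8612) / (1 - 0.8612), abs=1e-9)
        assert res.odds_ratio == pytest.approx(75.0)

    def test_perfect_agreement_has_unit_kappa(self):
        res = self._result(10, 0, 0, 90)
        assert res.kappa == pytest.approx(1.0)

    def test_kappa_matches_inter_rater_oracle(self, rng):
        # the 2x2 kappa formula against a generic inter-rater
        # implementation applied to the expanded label vectors
        for _ in range(500):
            a, b, c, d = rng.integers(0, 30, size=4)
            n = a + b + c + d
            if n == 0:
                continue
            rater1 = np.array([1] * (a + b) + [0] * (c + d))
            rater2 = np.array([1] * a + [0] * b + [1] * c + [0] * d)
            _, pe, kappa = kappa_from_counts(int(a), int(b), int(c), int(d))
            if pe >= 1.0 or len(set(rater1)) == 1 or len(set(rater2)) == 1:
                continue
            oracle = cohen_kappa_score(rater1, rater2)
            assert kappa == pytest.approx(oracle, abs=1e-12)

    def test_fisher_p_matches_enumeration_on_small_tables(self, rng):
        # two-sided Fisher p = total probability of tables (same
        # marginals) no more likely than the observed one
        for _ in range(40):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
            if a + b + c + d == 0 or a + b + c + d > 40:
                continue
            res = self._result(a, b, c, d)
            n, row1, col1 = a + b + c + d, a + b, a + c
            probs = [
                stats.hypergeom.pmf(k, n, row1, col1)
                for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
            ]
            observed = stats.hypergeom.pmf(a, n, row1, col1)
            expected = sum(p for p in probs if p <= observed * (1 + 1e-9))
            assert res.fisher_p == pytest.approx(expected, rel=1e-6)

    def test_independent_sets_have_near_zero_kappa(self, rng):
        # permutation null: random sets with fixed sizes over the universe
        universe = [f"p{i}" for i in range(200)]
        kappas = []
        for _ in range(300):
            set_a = set(rng.choice(universe, size=40, replace=False))
            set_b = set(rng.choice(universe, size=40, replace=False))
            kappas.append(pathway_agreement(set_a, set_b, universe).kappa)
        assert abs(np.mean(kappas)) < 0.02

    def test_haldane_correction_on_zero_cells(self):
        res = self._result(10, 0, 5, 85)
        assert res.odds_ratio == pytest.approx((10.5 * 85.5) / (0.5 * 5.5))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            pathway_agreement({"x"}, {"y"}, [])


@given(st.integers(min_value=0, max_value=2**32 - 1))
@settings(max_examples=40, deadline=None)
def test_kappa_bounded(seed):
    rng = np.random.default_rng(seed)
    a, b, c, d = (int(x) for x in rng.integers(0, 50, size=4))
    if a + b + c + d == 0:
        return
    _, pe, kappa = kappa_from_counts(a, b, c, d)
    if not np.isnan(kappa):
        assert -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12
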