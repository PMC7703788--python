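"""CASP-style scoring: ranking, precision, coverage, AUC, FP distance."""

import math

import numpy as np
import pytest

from contactlens import (
    ChainRecipe,
    ContactMap,
    DistanceMatrix,
    DomainSegment,
    LONG_RANGE,
    MEDIUM_RANGE,
    RANGES,
    SHORT_RANGE,
    contacts_from_distance,
    coverage_stat,
    evaluate_map,
    gen_chain,
    gen_predictions,
    mean_fp_distance,
    one_per_residue_filter,
    precision_topk,
    rank_pairs,
    restrict_to_domain,
    roc_auc,
    top_k,
)
from conftest import random_contact_map


def mann_whitney_auc(scores, labels):
    """Normalized rank-sum statistic: P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestRankPairs:
    def test_single_nonzero_pair_comes_first(self):
        prob = np.zeros((30, 30))
        prob[0, 28] = prob[28, 0] = 0.9
        ranked = rank_pairs(ContactMap(prob=prob), LONG_RANGE)
        assert ranked[0] == (1, 29, 0.9)

    def test_tie_break_is_deterministic(self):
        prob = np.zeros((40, 40))
        for i, j in [(0, 30), (2, 38), (5, 29)]:
            prob[i, j] = prob[j, i] = 0.5
        ranked = rank_pairs(ContactMap(prob=prob), LONG_RANGE)
        # equal probability: separation descending, then i ascending
        assert [r[:2] for r in ranked[:3]] == [(3, 39), (1, 31), (6, 30)]

    def test_equals_brute_force_sort(self, rng):
        cmap = random_contact_map(rng, 30)
        for rc in (SHORT_RANGE, MEDIUM_RANGE, LONG_RANGE):
            got = rank_pairs(cmap, rc)
            pairs = [
                (i + 1, j + 1, cmap.prob[i, j])
                for i in range(30)
                for j in range(i + 1, 30)
                if rc.contains(j - i)
            ]
            pairs.sort(key=lambda t: (-t[2], -(t[1] - t[0]), t[0], t[1]))
            assert got == pairs

    def test_band_edges(self):
        prob = np.zeros((40, 40))
        cmap = ContactMap(prob=prob)
        seps = {
            "short": {j - i for i, j, _ in rank_pairs(cmap, SHORT_RANGE)},
            "medium": {j - i for i, j, _ in rank_pairs(cmap, MEDIUM_RANGE)},
            "long": {j - i for i, j, _ in rank_pairs(cmap, LONG_RANGE)},
        }
        assert seps["short"] == set(range(6, 12))
        assert seps["medium"] == set(range(12, 24))
        assert seps["long"] == set(range(24, 40))


class TestPrecision:
    def test_perfect_prediction_is_100_everywhere(self, toy_native, toy_truth):
        for rc in RANGES.values():
            for frac in (0.1, 0.2, 0.5, 1.0, 2.0):
                p = precision_topk(toy_truth, toy_native, fraction=frac, range_class=rc)
                if p is not None:
                    assert p == 100.0

    def test_hand_placed_three_true_one_false(self):
        # 10-residue toy, short range band; 3 true + 1 false in the top 4
        L = 10
        d = np.full((L, L), 30.0)
        np.fill_diagonal(d, 0.0)
        for i, j in [(0, 6), (1, 7), (2, 8)]:
            d[i, j] = d[j, i] = 5.0
        native = DistanceMatrix(dist=d)
        prob = np.zeros((L, L))
        for q, (i, j) in zip((0.9, 0.8, 0.7, 0.6), [(0, 6), (1, 7), (2, 8), (3, 9)]):
            prob[i, j] = prob[j, i] = q
        pred = ContactMap(prob=prob)
        assert precision_topk(pred, native, k=4, range_class=SHORT_RANGE) == 75.0

    def test_unassessable_pairs_replaced_by_next_ranked(self):
        L = 10
        d = np.full((L, L), 30.0)
        np.fill_diagonal(d, 0.0)
        d[0, 6] = d[6, 0] = np.nan  # top pair unassessable
        d[1, 7] = d[7, 1] = 5.0
        native = DistanceMatrix(dist=d)
        prob = np.zeros((L, L))
        prob[0, 6] = prob[6, 0] = 0.9
        prob[1, 7] = prob[7, 1] = 0.8
        pred = ContactMap(prob=prob)
        assert precision_topk(pred, native, k=1, range_class=SHORT_RANGE) == 100.0

    def test_all_zero_prediction_assesses_nothing_by_default(self, toy_native):
        pred = ContactMap(prob=np.zeros((toy_native.L, toy_native.L)))
        assert precision_topk(pred, toy_native, range_class=LONG_RANGE) is None

    def test_all_zero_prediction_with_zero_ranking_matches_brute_force(self, toy_native):
        # zero scores everywhere: the tie-break alone fixes the top-k list
        pred = ContactMap(prob=np.zeros((toy_native.L, toy_native.L)))
        k = top_k(0.2, toy_native.L)
        got = precision_topk(
            pred, toy_native, k=k, range_class=LONG_RANGE, include_zero_prob=True
        )
        ranked = rank_pairs(pred, LONG_RANGE)[:k]
        expected = 100.0 * sum(
            toy_native.dist[i - 1, j - 1] < 8.0 for i, j, _ in ranked
        ) / k
        assert got == pytest.approx(expected)

    def test_precision_invariant_under_monotone_score_transform(self, toy_native, toy_truth):
        pred = gen_predictions(toy_truth, tp_signal=0.7, noise_sd=0.2, seed=5)
        squashed = ContactMap(prob=pred.prob**3)
        for rc in RANGES.values():
            assert precision_topk(pred, toy_native, range_class=rc) == precision_topk(
                squashed, toy_native, range_class=rc
            )

    def test_k_is_floor_of_fraction_min_one(self):
        assert top_k(0.2, 47) == 9
        assert top_k(0.2, 3) == 1
        assert top_k(2.0, 10) == 20


class TestCoverage:
    def test_perfect_prediction_with_large_k_reaches_100(self, toy_native, toy_truth):
        cov = coverage_stat(toy_truth, toy_native, k=10**6, range_class=LONG_RANGE)
        assert cov == 100.0

    def test_zero_k_gives_zero(self, toy_native, toy_truth):
        assert coverage_stat(toy_truth, toy_native, k=0, range_class=LONG_RANGE) == 0.0

    def test_non_decreasing_in_k_and_matches_brute_force(self, rng, toy_native, toy_truth):
        pred = gen_predictions(toy_truth, tp_signal=0.5, noise_sd=0.3, seed=11)
        last = -1.0
        for k in range(0, 60, 5):
            cov = coverage_stat(pred, toy_native, k=k, range_class=LONG_RANGE)
            assert cov >= last
            last = cov
            # brute force: count true contacts among top-k predicted pairs
            ranked = [p for p in rank_pairs(pred, LONG_RANGE) if p[2] > 0][:k]
            tp = sum(toy_native.dist[i - 1, j - 1] < 8.0 for i, j, _ in ranked)
            n_native = sum(
                toy_native.dist[i, j] < 8.0
                for i in range(toy_native.L)
                for j in range(i + 24, toy_native.L)
            )
            assert cov == pytest.approx(100.0 * tp / n_native)


class TestAuc:
    def test_perfect_separation_is_one(self, toy_native, toy_truth):
        assert roc_auc(toy_truth, toy_native, LONG_RANGE) == pytest.approx(1.0)

    def test_equals_mann_whitney_oracle(self, rng, toy_native):
        truth = contacts_from_distance(toy_native)
        for seed in range(5):
            pred = gen_predictions(truth, tp_signal=0.4, noise_sd=0.3, seed=seed)
            pairs = rank_pairs(pred, SHORT_RANGE)
            scores = [p for _, _, p in pairs]
            labels = [toy_native.dist[i - 1, j - 1] < 8.0 for i, j, _ in pairs]
            assert len(pairs) <= 200
            got = roc_auc(pred, toy_native, SHORT_RANGE)
            assert got == pytest.approx(mann_whitney_auc(scores, labels))

    def test_label_independent_scores_near_half(self, toy_native, toy_truth):
        rng = np.random.default_rng(99)
        aucs = []
        for seed in range(200):
            pred = gen_predictions(toy_truth, tp_signal=0.0, noise_sd=0.3, seed=seed)
            a = roc_auc(pred, toy_native, LONG_RANGE)
            aucs.append(a)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_degenerate_labels_give_none(self):
        L = 30
        d = np.full((L, L), 40.0)
        np.fill_diagonal(d, 0.0)
        native = DistanceMatrix(dist=d)  # no contacts at all
        pred = ContactMap(prob=np.zeros((L, L)))
        assert roc_auc(pred, native, LONG_RANGE) is None


class TestMeanFpDistance:
    def test_no_false_positives_gives_none(self, toy_native, toy_truth):
        assert mean_fp_distance(toy_truth, toy_native, range_class=LONG_RANGE) is None

    def test_single_fp_at_known_distance(self):
        L = 30
        d = np.full((L, L), 30.0)
        np.fill_diagonal(d, 0.0)
        d[0, 28] = d[28, 0] = 14.1
        native = DistanceMatrix(dist=d)
        prob = np.zeros((L, L))
        prob[0, 28] = prob[28, 0] = 0.9
        pred = ContactMap(prob=prob)
        assert mean_fp_distance(pred, native, k=1, range_class=LONG_RANGE) == pytest.approx(14.1)

    def test_matches_brute_force_on_fixture(self, toy_native, toy_truth):
        pred = gen_predictions(toy_truth, tp_signal=0.5, noise_sd=0.3, seed=3)
        k = top_k(0.2, toy_native.L)
        got = mean_fp_distance(pred, toy_native, range_class=LONG_RANGE)
        ranked = [p for p in rank_pairs(pred, LONG_RANGE) if p[2] > 0][:k]
        fps = [
            toy_native.dist[i - 1, j - 1]
            for i, j, _ in ranked
            if not toy_native.dist[i - 1, j - 1] < 8.0
        ]
        if fps:
            assert got == pytest.approx(float(np.mean(fps)))
        else:  # pragma: no cover
            assert got is None


class TestDomainRestriction:
    def test_full_length_segment_is_identity(self, toy_native, toy_truth):
        seg = DomainSegment(1, toy_native.L, "full")
        np.testing.assert_array_equal(
            restrict_to_domain(toy_truth, seg).prob, toy_truth.prob
        )
        np.testing.assert_array_equal(
            restrict_to_domain(toy_native, seg).dist, toy_native.dist
        )

    def test_toy_submatrix(self):
        prob = np.zeros((10, 10))
        prob[4, 9] = prob[9, 4] = 0.8
        cmap = ContactMap(prob=prob)
        sub = restrict_to_domain(cmap, DomainSegment(5, 10))
        assert sub.L == 6
        assert sub.prob[0, 5] == pytest.approx(0.8)

    def test_out_of_range_segment_rejected(self, toy_truth):
        with pytest.raises(ValueError):
            restrict_to_domain(toy_truth, DomainSegment(5, 99))

    def test_separations_keep_full_chain_meaning(self, toy_native, toy_truth):
        # both residues of an assessed pair share the index shift, so the
        # domain submatrix scores exactly the in-segment pairs of the full map
        seg = DomainSegment(5, 36)
        sub_p = restrict_to_domain(toy_truth, seg)
        sub_n = restrict_to_domain(toy_native, seg)
        got = precision_topk(sub_p, sub_n, fraction=0.5, range_class=LONG_RANGE)
        if got is not None:
            assert got == 100.0


class TestOnePerResidueFilter:
    def test_disjoint_pairs_unchanged(self):
        ranked = [(1, 30, 0.9), (2, 40, 0.8), (3, 50, 0.7)]
        assert one_per_residue_filter(ranked) == ranked

    def test_shared_residue_dropped(self):
        ranked = [(1, 30, 0.9), (1, 40, 0.8), (2, 30, 0.7), (5, 50, 0.6)]
        assert one_per_residue_filter(ranked) == [(1, 30, 0.9), (5, 50, 0.6)]

    def test_matches_greedy_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 40))
            ranked = [
                (int(rng.integers(1, 30)), int(rng.integers(30, 60)), float(p))
                for p in np.sort(rng.random(n))[::-1]
            ]
            used, expected = set(), []
            for i, j, p in ranked:
                if i not in used and j not in used:
                    expected.append((i, j, p))
                    used |= {i, j}
            assert one_per_residue_filter(ranked) == expected


class TestRandomScoreBaseline:
    def test_shuffled_scores_hit_band_density(self, toy_native):
        """Uniform random scores sample band pairs uniformly, so mean top-k
        precision estimates the band contact density (within 3 s.e.)."""
        L = toy_native.L
        iu, ju = np.triu_indices(L, k=1)
        keep = (ju - iu) >= 24
        labels = toy_native.dist[iu[keep], ju[keep]] < 8.0
        density = labels.mean()
        rng = np.random.default_rng(4242)
        precisions = []
        for _ in range(200):
            prob = np.zeros((L, L))
            vals = rng.uniform(0.01, 1.0, size=keep.sum())
            prob[iu[keep], ju[keep]] = vals
            prob = prob + prob.T
            pred = ContactMap(prob=prob)
            precisions.append(
                precision_topk(pred, toy_native, fraction=0.2, range_class=LONG_RANGE)
            )
        mean = np.mean(precisions)
        se = np.std(precisions, ddof=1) / np.sqrt(len(precisions))
        assert abs(mean - 100.0 * density) <= 3 * se + 1e-9


class TestEvaluateMap:
    def test_scorecard_structure_and_perfect_values(self, toy_native, toy_truth):
        card = evaluate_map(toy_truth, toy_native)
        assert set(card) == {"short", "medium", "long"}
        for entry in card.values():
            for key, val in entry.items():
                if key.startswith("precision_") and val is not None:
                    assert val == 100.0
            if entry["auc"] is not None:
                assert entry["auc"] == pytest.approx(1.0)
            assert entry["mean_fp_distance_topL5"] is None
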