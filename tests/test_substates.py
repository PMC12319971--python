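"""Substate detection: thresholding, Louvain, occupancy, chi-square
separability, threshold selection, and the k-means control."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from brainstates.similarity import SubtractionMatrix
from brainstates.substates import (
    AffiliationVector,
    kmeans_control,
    louvain_communities,
    modularity,
    occupancy,
    occupancy_minutes,
    retained_substates,
    separability_chi2,
    threshold_matrix,
    threshold_sweep,
)


def _sub(values, inj, tr=2.0):
    return SubtractionMatrix(np.asarray(values, float), tr_seconds=tr, injection_volume=inj)


def _block_matrix(sizes, within=1.0, between=0.0):
    labels = np.repeat(np.arange(len(sizes)), sizes)
    W = np.where(labels[:, None] == labels[None, :], within, between)
    np.fill_diagonal(W, 0.0)
    return W, labels + 1


class TestThresholdMatrix:
    def test_entry_at_threshold_kept(self):
        S = _sub([[0, 0.25], [0.25, 0]], inj=1)
        W = threshold_matrix(S, 0.25)
        assert W[0, 1] == 0.25

    def test_negative_entries_zeroed(self):
        S = _sub([[0, -0.4], [-0.4, 0]], inj=1)
        assert np.all(threshold_matrix(S, 0.25) == 0)

    def test_subthreshold_zeroed_and_absolute_variant(self):
        S = _sub([[0, 0.1, -0.4], [0.1, 0, 0.3], [-0.4, 0.3, 0]], inj=1)
        W = threshold_matrix(S, 0.25)
        assert W[0, 1] == 0 and W[0, 2] == 0 and W[1, 2] == 0.3
        Wa = threshold_matrix(S, 0.25, use_absolute=True)
        assert Wa[0, 2] == -0.4  # kept at its signed value

    def test_out_of_range_warns_not_errors(self):
        S = _sub([[0, 0.5], [0.5, 0]], inj=1)
        with pytest.warns(UserWarning, match="sweep range"):
            threshold_matrix(S, 0.4)

    def test_monotone_sparsification(self, rng):
        vals = rng.uniform(-0.5, 0.5, (30, 30))
        vals = (vals + vals.T) / 2
        S = _sub(vals, inj=10)
        totals = [threshold_matrix(S, r).sum() for r in np.arange(0.20, 0.301, 0.01)]
        assert all(a >= b for a, b in zip(totals, totals[1:]))


class TestLouvain:
    def test_perfect_two_block_every_restart(self):
        W, truth = _block_matrix([10, 10])
        for seed in range(5):
            affil, q = louvain_communities(W, seed=seed, n_restarts=1)
            assert affil.k == 2
            assert adjusted_rand_score(truth, affil.labels) == 1.0

    def test_planted_five_block_with_noise(self, rng):
        W, truth = _block_matrix([20, 15, 25, 18, 22], within=0.8, between=0.05)
        W = W * rng.uniform(0.5, 1.5, W.shape)
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        affil, _ = louvain_communities(W, seed=0, n_restarts=20)
        assert adjusted_rand_score(truth, affil.labels) >= 0.9

    def test_agrees_with_igraph_multilevel(self, rng):
        """Independent cross-check against igraph's Louvain on the same graph."""
        igraph = pytest.importorskip("igraph")
        W, truth = _block_matrix([15, 10, 12], within=0.8, between=0.05)
        W = W * rng.uniform(0.5, 1.5, W.shape)
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        affil, q = louvain_communities(W, seed=3, n_restarts=20)
        import random

        random.seed(0)
        g = igraph.Graph.Weighted_Adjacency(W.tolist(), mode="undirected")
        ig_part = np.asarray(g.community_multilevel(weights="weight").membership)
        assert adjusted_rand_score(ig_part, affil.labels) == 1.0
        assert q == pytest.approx(modularity(W, ig_part), abs=1e-10)

    def test_quality_at_least_trivial_partition(self, rng):
        vals = rng.uniform(-0.3, 0.8, (40, 40))
        W = (vals + vals.T) / 2
        np.fill_diagonal(W, 0)
        affil, q = louvain_communities(W, seed=1, n_restarts=5)
        assert q >= modularity(W, np.zeros(40)) - 1e-12

    def test_signed_treatments_differ_and_run(self):
        W, _ = _block_matrix([8, 8], within=1.0, between=-0.5)
        for treatment in ("symmetric", "asymmetric"):
            affil, q = louvain_communities(W, neg_treatment=treatment, seed=0, n_restarts=5)
            assert affil.k == 2
        with pytest.raises(ValueError, match="neg_treatment"):
            louvain_communities(W, neg_treatment="bogus")

    def test_zero_strength_volumes_become_singletons(self):
        W, _ = _block_matrix([6, 6])
        W[3, :] = 0
        W[:, 3] = 0
        affil, _ = louvain_communities(W, seed=0, n_restarts=3)
        assert affil.singleton_volumes == [4]
        assert np.sum(affil.labels == affil.labels[3]) == 1

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty graph"):
            louvain_communities(np.zeros((5, 5)))


class TestOccupancy:
    def _affil(self, labels):
        labels = np.asarray(labels)
        return AffiliationVector(labels, k=int(labels.max()))

    def test_fraction_and_partition(self):
        labels = np.concatenate([np.full(60, 1), np.full(180, 2), np.full(60, 1), np.full(180, 3)])
        summ = occupancy(self._affil(labels), injection_volume=240)
        assert summ[0].pre_occupancy == 60 / 240
        assert summ[0].post_occupancy == 60 / 240
        assert sum(s.pre_occupancy for s in summ) == pytest.approx(1.0)
        assert sum(s.post_occupancy for s in summ) == pytest.approx(1.0)

    def test_minutes_are_occupancy_times_period(self):
        labels = np.concatenate([np.full(60, 1), np.full(180, 2), np.full(240, 2)])
        summ = occupancy(self._affil(labels), injection_volume=240, tr_seconds=2.0)
        assert summ[0].pre_minutes == pytest.approx((60 / 240) * 8.0)
        assert summ[1].post_minutes == pytest.approx(1.0 * 8.0)  # 240 post volumes

    @pytest.mark.parametrize(
        "frac, period_min, minutes",
        [(0.34, 8.0, 2.7), (0.10, 20.0, 2.0), (0.19, 20.0, 3.8), (0.18, 20.0, 3.6)],
    )
    def test_printed_occupancy_to_minutes_conversion(self, frac, period_min, minutes):
        assert occupancy_minutes(frac, period_min) == minutes


class TestSeparability:
    def _affil(self, labels):
        labels = np.asarray(labels)
        return AffiliationVector(labels, k=int(labels.max()))

    def test_equal_occupancy_gives_zero_chi2(self):
        labels = np.tile([1, 2], 100)
        res = separability_chi2(self._affil(labels), injection_volume=100)
        assert res.omnibus_chi2 == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_2x2(self):
        # [[30,10],[10,30]]: all expected counts 20 -> chi2 = 4 * 100/20 = 20
        labels = np.concatenate([np.full(30, 1), np.full(10, 2), np.full(10, 1), np.full(30, 2)])
        res = separability_chi2(self._affil(labels), injection_volume=40)
        assert res.per_state[1][0] == pytest.approx(20.0)
        assert res.omnibus_chi2 == pytest.approx(20.0)
        assert res.df == 1

    def test_omnibus_matches_cellwise_oracle(self, rng):
        for _ in range(20):
            labels = rng.integers(1, 5, size=120)
            _, labels = np.unique(labels, return_inverse=True)
            affil = self._affil(labels + 1)
            inj = int(rng.integers(30, 90))
            res = separability_chi2(affil, injection_volume=inj)
            table = np.array(
                [
                    [np.sum((labels + 1 == s) & (np.arange(1, 121) <= inj)),
                     np.sum((labels + 1 == s) & (np.arange(1, 121) > inj))]
                    for s in range(1, affil.k + 1)
                ],
                dtype=float,
            )
            table = table[table.sum(1) > 0]
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            oracle = np.sum((table - expected) ** 2 / expected)
            assert res.omnibus_chi2 == pytest.approx(oracle, rel=1e-12)

    def test_per_state_p_matches_textbook_oracle(self, rng):
        for _ in range(20):
            labels = rng.integers(1, 4, size=80)
            _, labels = np.unique(labels, return_inverse=True)
            affil = self._affil(labels + 1)
            res = separability_chi2(affil, injection_volume=40)
            for s in range(1, affil.k + 1):
                pre = np.sum((labels + 1 == s) & (np.arange(80) < 40))
                post = np.sum((labels + 1 == s) & (np.arange(80) >= 40))
                rest_pre, rest_post = 40 - pre, 40 - post
                table = np.array([[pre, post], [rest_pre, rest_post]], dtype=float)
                expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
                if expected.min() == 0:
                    continue
                chi2 = np.sum((table - expected) ** 2 / expected)
                assert res.per_state[s][0] == pytest.approx(chi2, rel=1e-12)
                assert res.per_state[s][1] == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-12)

    def test_sum_method_aggregates_per_state(self):
        labels = np.concatenate([np.full(30, 1), np.full(10, 2), np.full(10, 1), np.full(30, 2)])
        res = separability_chi2(self._affil(labels), injection_volume=40, method="sum")
        assert res.omnibus_chi2 == pytest.approx(sum(c for c, _ in res.per_state.values()))


class TestRetained:
    def _summ(self, label, pre, post, p):
        from brainstates.substates import SubstateSummary

        return SubstateSummary(label, pre, post, pre * 8, post * 20, chi2=0.0, p_value=p)

    def test_low_occupancy_discarded_despite_significance(self):
        kept = retained_substates([self._summ(1, 0.03, 0.02, 1e-6)])
        assert kept == []

    def test_significant_and_occupied_retained(self):
        kept = retained_substates([self._summ(1, 0.06, 0.19, 0.01)])
        assert kept == [1]

    def test_nonsignificant_never_retained(self):
        kept = retained_substates([self._summ(1, 0.5, 0.5, 1.0), self._summ(2, 0.5, 0.5, 1.0)])
        assert kept == []


class TestSweep:
    def test_balanced_blocks_yield_no_retained_states(self):
        """Blocks straddling the injection evenly are never pre/post
        separable, so no threshold retains a substate."""
        T, inj = 80, 40
        half = np.concatenate([np.full(20, 0), np.full(20, 1)])
        labels = np.concatenate([half, half])  # each block half pre, half post
        W = np.where(labels[:, None] == labels[None, :], 0.5, 0.0)
        np.fill_diagonal(W, 0)
        sweep = threshold_sweep(_sub(W, inj), seed=0, n_restarts=5)
        assert all(r.n_retained == 0 for r in sweep.rows)

    def test_all_empty_rejected(self):
        sweep_input = _sub(np.zeros((20, 20)), inj=10)
        with pytest.raises(ValueError, match="empty graph"):
            threshold_sweep(sweep_input, seed=0, n_restarts=2)

    def test_selection_tie_break_prefers_smaller_threshold(self, small_subtraction):
        sweep = threshold_sweep(small_subtraction, seed=1, n_restarts=10)
        best = max(r.n_retained for r in sweep.rows)
        candidates = [r for r in sweep.rows if r.n_retained == best]
        top_chi2 = max(
            (r.omnibus_chi2 for r in candidates if np.isfinite(r.omnibus_chi2)), default=np.nan
        )
        tied = [r for r in candidates if r.omnibus_chi2 == pytest.approx(top_chi2)]
        assert sweep.selected.threshold == min(r.threshold for r in tied)


class TestKMeansControl:
    def test_perfect_three_block_recovered(self):
        W, truth = _block_matrix([10, 12, 8])
        affil, _ = kmeans_control(_sub(W, inj=15), k=3, seed=0)
        assert adjusted_rand_score(truth, affil.labels) == 1.0

    def test_best_replicate_by_inertia(self, small_subtraction):
        affil, inertias = kmeans_control(small_subtraction, k=5, replicates=10, seed=2)
        assert inertias.size == 10
        # WCSS of the returned partition equals the replicate minimum
        X = small_subtraction.values
        wcss = sum(
            np.sum((X[affil.labels == s] - X[affil.labels == s].mean(axis=0)) ** 2)
            for s in range(1, 6)
        )
        assert wcss == pytest.approx(np.min(inertias), rel=1e-6)
        assert all(wcss <= i + 1e-6 for i in inertias)

    def test_planted_states_recovered(self, rng):
        W, truth = _block_matrix([30, 25, 35, 28, 32], within=0.6, between=0.0)
        W += 0.1 * rng.standard_normal(W.shape)
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        affil, _ = kmeans_control(_sub(W, inj=60), k=5, seed=3)
        assert adjusted_rand_score(truth, affil.labels) >= 0.9

    def test_k_exceeding_volumes_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_control(_sub(np.zeros((4, 4)), inj=2), k=10)
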