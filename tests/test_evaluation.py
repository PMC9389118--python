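import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from cmipred.evaluation import (
    ScoredPairs,
    auc_score,
    aupr_score,
    compute_metrics,
    confusion_metrics,
    cross_validate,
    degree_baseline_scores,
    rank_candidates,
    sweep,
)
from cmipred.graph_data import subgraph_with_edges
from cmipred.model import ModelConfig, init_params
from cmipred.training import TrainConfig

from _oracles import pairwise_auc_oracle, step_sum_ap_oracle
from conftest import BENCH_FOLD_SEED, BENCH_MODEL, SWEEP_TRAIN


def _sp(scores, labels):
    return ScoredPairs(pairs=[], scores=np.asarray(scores, float),
                       labels=np.asarray(labels))


scored_instances = st.integers(0, 2**32 - 1).map(
    lambda s: np.random.default_rng(s)
).map(
    lambda r: (
        np.round(r.normal(size=(n := int(r.integers(2, 50)))), 1),  # ties likely
        np.concatenate([[0, 1], r.integers(0, 2, size=n - 2)]),
    )
)


class TestAucScore:
    def test_perfect_separation(self):
        assert auc_score(_sp([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc_score(_sp([0.5] * 6, [0, 1, 0, 1, 0, 1])) == 0.5

    def test_four_point_example(self):
        assert auc_score(_sp([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score(_sp([0.1, 0.2], [1, 1]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(scored_instances)
    def test_equals_bruteforce_pair_ordering(self, inst):
        scores, labels = inst
        sp = _sp(scores, labels)
        assert auc_score(sp) == pytest.approx(pairwise_auc_oracle(scores, labels))
        assert auc_score(sp) == pytest.approx(roc_auc_score(labels, scores))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scored_instances)
    def test_invariant_under_monotone_transform(self, inst):
        scores, labels = inst
        transformed = np.exp(3.0 * scores) + 1.0
        assert auc_score(_sp(scores, labels)) == pytest.approx(
            auc_score(_sp(transformed, labels))
        )


class TestAuprScore:
    def test_perfect_ranking(self):
        assert aupr_score(_sp([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])) == 1.0

    def test_worst_ranking_approaches_prevalence(self):
        n, p = 2000, 4
        scores = np.arange(n, dtype=float)
        labels = np.concatenate([np.ones(p), np.zeros(n - p)])  # positives last
        closed = sum((i / p - (i - 1) / p) * (i / (n - p + i)) for i in range(1, p + 1))
        ap = aupr_score(_sp(scores, labels))
        assert ap == pytest.approx(closed)
        assert ap < p / n  # bounded by prevalence for the worst ranking
        assert ap > p / (4 * n)

    def test_four_point_example_matches_step_sum(self):
        scores, labels = [0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]
        assert aupr_score(_sp(scores, labels)) == pytest.approx(
            step_sum_ap_oracle(scores, labels)
        )

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            aupr_score(_sp([0.1, 0.2], [0, 0]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(scored_instances)
    def test_equals_step_sum_enumeration(self, inst):
        scores, labels = inst
        ap = aupr_score(_sp(scores, labels))
        assert ap == pytest.approx(step_sum_ap_oracle(list(scores), list(labels)))
        assert ap == pytest.approx(average_precision_score(labels, scores))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scored_instances)
    def test_invariant_under_monotone_transform(self, inst):
        scores, labels = inst
        assert aupr_score(_sp(scores, labels)) == pytest.approx(
            aupr_score(_sp(2.0 * scores - 5.0, labels))
        )


class TestConfusionMetrics:
    def test_direct_arithmetic_example(self):
        # TP=3, FP=1, TN=4, FN=2
        scores = [1, 1, 1, 1] + [-1, -1, -1, -1, -1, -1]
        labels = [1, 1, 1, 0] + [0, 0, 0, 0, 1, 1]
        rep = confusion_metrics(_sp(scores, labels), threshold=0.0)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (3, 1, 4, 2)
        assert rep.acc == pytest.approx(0.7)
        assert rep.pre == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.6)
        assert rep.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_perfect_classification(self):
        rep = confusion_metrics(_sp([1] * 5 + [-1] * 5, [1] * 5 + [0] * 5))
        assert rep.acc == rep.pre == rep.recall == rep.f1 == 1.0

    def test_published_fold_precision_recall_consistency(self):
        # fold-level precision/recall pairs reported for the circBank
        # benchmark; F1 must follow the harmonic-mean identity at 4 d.p.
        pre, rec, f1 = 0.9390, 0.8289, 0.8805
        assert round(2 * pre * rec / (pre + rec), 4) == f1

    def test_degenerate_denominators_reported_as_none(self):
        rep = confusion_metrics(_sp([-1.0, -2.0], [0, 1]), threshold=0.0)
        assert rep.pre is None and rep.f1 is None
        assert rep.recall == 0.0
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (0, 0, 1, 1)


class TestCrossValidate:
    def test_metrics_internally_consistent(self, planted_cv):
        for rep in planted_cv.per_fold:
            total = rep.tp + rep.fp + rep.tn + rep.fn
            assert rep.acc == pytest.approx((rep.tp + rep.tn) / total)
            assert rep.f1 == pytest.approx(
                2 * rep.pre * rep.recall / (rep.pre + rep.recall), abs=1e-12
            )

    def test_averages_are_exact_means(self, planted_cv):
        for key in ("auc", "aupr", "f1"):
            vals = [getattr(r, key) for r in planted_cv.per_fold]
            assert planted_cv.averages[key] == np.mean(vals)

    def test_beats_degree_product_baseline(self, planted, planted_cv):
        base_aucs = []
        for fs in planted_cv.folds:
            tg = subgraph_with_edges(planted.graph, fs.train_pos)
            pairs = sorted(fs.test_pos) + sorted(fs.test_neg)
            labels = np.concatenate(
                [np.ones(len(fs.test_pos)), np.zeros(len(fs.test_neg))]
            )
            base_aucs.append(
                auc_score(ScoredPairs(pairs, degree_baseline_scores(tg, pairs), labels))
            )
        assert planted_cv.averages["auc"] > np.mean(base_aucs)


class TestSweep:
    def test_single_value_single_row(self, planted):
        tc = TrainConfig(max_epochs=3, patience=1, batch_size=256, seed=0)
        mc = ModelConfig(K=1, D=8, seed=0)
        table = sweep("K", [1], planted.graph, mc, tc, k=2, seed=BENCH_FOLD_SEED)
        assert len(table) == 1 and table.iloc[0]["K"] == 1
        assert 0.0 <= table.iloc[0]["AUC"] <= 1.0

    def test_reproducible_across_runs(self, planted):
        tc = TrainConfig(max_epochs=3, patience=1, batch_size=256, seed=0)
        mc = ModelConfig(K=1, D=8, seed=0)
        a = sweep("D", [4, 8], planted.graph, mc, tc, k=2, seed=2)
        b = sweep("D", [4, 8], planted.graph, mc, tc, k=2, seed=2)
        assert a.equals(b)

    def test_unknown_parameter_rejected(self, planted):
        with pytest.raises(ValueError):
            sweep("lr", [1], planted.graph, BENCH_MODEL, SWEEP_TRAIN)


class TestRankCandidates:
    @pytest.fixture()
    def trained_toy(self, toy):
        cfg = ModelConfig(K=1, D=4, seed=0)
        return init_params(toy, cfg), cfg

    def test_top_k_larger_than_candidates_returns_all(self, toy, trained_toy):
        params, cfg = trained_toy
        ranked = rank_candidates(params, toy, "circ_2", cfg, top_k=50,
                                 exclude_known=False)
        assert len(ranked) == toy.m

    def test_top_score_is_one_after_minmax(self, toy, trained_toy):
        params, cfg = trained_toy
        ranked = rank_candidates(params, toy, "circ_0", cfg, exclude_known=False)
        assert ranked[0][1] == pytest.approx(1.0)
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_known_partners_excluded(self, toy, trained_toy):
        params, cfg = trained_toy
        ranked = rank_candidates(params, toy, "circ_0", cfg, exclude_known=True)
        ids = {cid for cid, _ in ranked}
        assert ids.isdisjoint({"mir_0", "mir_1"})  # training partners of circ 0

    def test_unknown_query_rejected(self, toy, trained_toy):
        params, cfg = trained_toy
        with pytest.raises(KeyError):
            rank_candidates(params, toy, "nonexistent", cfg)

    def test_top_candidates_enriched_for_planted_affinity(self, planted):
        # noiseless planted graph: a trained model's top-10 for a query
        # should score far above the candidate average in hidden affinity
        from cmipred.synthetic import SyntheticConfig, generate_planted_graph
        from cmipred.training import fit

        pg = generate_planted_graph(
            SyntheticConfig(n=60, m=40, latent_dim=3, density=0.08,
                            noise_flip_prob=0.0, seed=2)
        )
        mc = ModelConfig(K=2, D=16, seed=0)
        tc = TrainConfig(max_epochs=150, patience=30, batch_size=256, seed=0)
        params, _ = fit(pg.graph, pg.graph.edges, mc, tc)
        cm = pg.graph.index_map
        query = cm.circ_ids[0]
        ranked = rank_candidates(params, pg.graph, query, mc, top_k=10,
                                 exclude_known=True)
        known = {v for (u, v) in pg.graph.edges if u == 0}
        candidates = [j for j in range(pg.graph.m) if j not in known]
        top_truth = np.mean([pg.truth_scores[0, cm.mir_index[cid]] for cid, _ in ranked])
        all_truth = np.mean([pg.truth_scores[0, j] for j in candidates])
        assert top_truth > all_truth


class TestComputeMetrics:
    def test_bundles_ranking_and_threshold_metrics(self):
        sp = _sp([0.9, 0.8, -0.2, -0.1], [1, 1, 0, 0])
        rep = compute_metrics(sp, threshold=0.0)
        assert rep.auc == 1.0 and rep.aupr == 1.0
        assert rep.acc == 1.0 and (rep.tp, rep.tn) == (2, 2)
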