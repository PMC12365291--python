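"""Negative sampling, split hygiene, metrics, bootstrap and the training loop."""

import numpy as np
import pytest

from ghcdti.config import RunConfig
from ghcdti.synthetic import SyntheticSpec, generate
from ghcdti.train_eval import (bootstrap_ci, evaluate, labeled_pairs,
                               make_split_plan, run_plan, sample_negatives,
                               train)


def auc_concordance_oracle(scores, labels):
    """O(n^2) pairwise concordance with ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def aupr_step_oracle(scores, labels):
    """Step-wise area: sum over recall increments of the precision there."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    labels = np.asarray(labels)[order]
    scores = np.asarray(scores)[order]
    P = labels.sum()
    area, tp, fp = 0.0, 0, 0
    i = 0
    n = len(labels)
    prev_recall = 0.0
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:
            j += 1
        tp += labels[i:j].sum()
        fp += (j - i) - labels[i:j].sum()
        recall = tp / P
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


class TestSampleNegatives:
    def test_count_and_no_overlap(self):
        pos = [(0, 0), (1, 1), (2, 2), (3, 3), (0, 4)]
        negs = sample_negatives(pos, 8, 8, ratio=10, seed=0)
        assert len(negs) == 50
        assert not set(negs) & set(pos)
        assert len(set(negs)) == 50

    def test_deterministic_per_seed(self):
        pos = [(0, 0), (1, 1)]
        a = sample_negatives(pos, 10, 10, ratio=10, seed=7)
        b = sample_negatives(pos, 10, 10, ratio=10, seed=7)
        assert a == b
        c = sample_negatives(pos, 10, 10, ratio=10, seed=8)
        assert a != c

    def test_uniform_inclusion_without_exclusion_rule(self):
        pos = [(0, 0)]
        counts = {}
        n_rep = 2000
        for seed in range(n_rep):
            for pair in sample_negatives(pos, 4, 4, ratio=10, seed=seed):
                counts[pair] = counts.get(pair, 0) + 1
        # 15 candidates, 10 drawn each time: inclusion prob 2/3
        p = 10 / 15
        sigma = np.sqrt(n_rep * p * (1 - p))
        for pair, c in counts.items():
            assert abs(c - n_rep * p) < 4 * sigma, (pair, c)

    def test_similarity_exclusion_rule(self):
        # drug 1 is near-identical to drug 0 which interacts with protein 0;
        # (1, 0) must never be drawn as a negative
        pos = [(0, 0)]
        sim_drug = np.eye(3)
        sim_drug[0, 1] = sim_drug[1, 0] = 0.95
        seen = set()
        for seed in range(50):
            seen |= set(sample_negatives(pos, 3, 3, ratio=2, sim_drug=sim_drug,
                                         excl_cutoff=0.8, seed=seed))
        assert (1, 0) not in seen
        assert (2, 0) in seen  # dissimilar drug stays eligible

    def test_insufficient_candidates_reports_achievable(self):
        pos = [(i, j) for i in range(3) for j in range(3) if (i, j) != (0, 0)]
        with pytest.raises(ValueError, match="insufficient"):
            sample_negatives(pos, 3, 3, ratio=10, seed=0)


class TestSplitPlans:
    def _pairs(self, rng, n_pos=100, n_neg=1000, n_drug=40, n_prot=50):
        seen = set()
        rows = []
        while len(rows) < n_pos + n_neg:
            d, p = rng.integers(n_drug), rng.integers(n_prot)
            if (d, p) in seen:
                continue
            seen.add((d, p))
            rows.append((d, p, 1 if len(rows) < n_pos else 0))
        return np.asarray(rows)

    def test_standard_folds_stratified_to_one(self):
        rng = np.random.default_rng(0)
        pairs = self._pairs(rng)
        plan = make_split_plan(pairs, "standard", k=10, seed=0)
        pos_counts = [f.test_pairs[:, 2].sum() for f in plan.folds]
        assert max(pos_counts) - min(pos_counts) <= 1
        assert all(c == 10 for c in pos_counts)  # 100 positives, k=10

    def test_folds_partition_pair_set(self):
        rng = np.random.default_rng(1)
        pairs = self._pairs(rng)
        plan = make_split_plan(pairs, "standard", k=10, seed=0)
        seen = [tuple(r) for f in plan.folds for r in f.test_pairs]
        assert len(seen) == len(pairs)
        assert set(seen) == {tuple(r) for r in pairs}

    def test_cold_drug_entity_isolation(self):
        rng = np.random.default_rng(2)
        pairs = self._pairs(rng)
        plan = make_split_plan(pairs, "cold_drug", k=5, seed=0, n_drug=40, n_prot=50)
        for f in plan.folds:
            test_drugs = set(f.test_pairs[:, 0])
            train_drugs = set(f.train_pairs[:, 0]) | set(f.valid_pairs[:, 0])
            assert not test_drugs & train_drugs

    def test_cold_target_entity_isolation_many_plans(self):
        for seed in range(20):
            rng = np.random.default_rng(seed + 100)
            pairs = self._pairs(rng, n_pos=60, n_neg=400)
            plan = make_split_plan(pairs, "cold_target", k=4, seed=seed,
                                   n_drug=40, n_prot=50)
            for f in plan.folds:
                test_prots = set(f.test_pairs[:, 1])
                other = set(f.train_pairs[:, 1]) | set(f.valid_pairs[:, 1])
                assert not test_prots & other

    def test_invalid_mode_and_k_rejected(self):
        pairs = np.array([[0, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError):
            make_split_plan(pairs, "warm_ish", k=2)
        with pytest.raises(ValueError):
            make_split_plan(pairs, "standard", k=1)


class TestEvaluate:
    def test_perfect_separation(self):
        auc, aupr = evaluate(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert auc == 1.0 and aupr == 1.0

    def test_all_ties_give_half_auc(self):
        auc, _ = evaluate(np.ones(10), np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 1]))
        assert np.isclose(auc, 0.5)

    def test_matches_concordance_and_step_oracles(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(20, 200)
            scores = np.round(rng.random(n), 2)  # ties likely
            labels = (rng.random(n) < 0.3).astype(int)
            if labels.sum() in (0, n):
                continue
            auc, aupr = evaluate(scores, labels)
            assert np.isclose(auc, auc_concordance_oracle(scores, labels), atol=1e-10)
            assert np.isclose(aupr, aupr_step_oracle(scores, labels), atol=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0.5, 0.6]), np.array([1, 1]))


class TestBootstrapCI:
    def test_perfect_classifier_degenerate_interval(self):
        scores = np.array([0.9] * 20 + [0.1] * 80)
        labels = np.array([1] * 20 + [0] * 80)
        ci = bootstrap_ci(scores, labels, B=200, seed=0)
        assert ci["auc"] == (1.0, 1.0)
        assert ci["aupr"] == (1.0, 1.0)

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        labels = (rng.random(300) < 0.2).astype(int)
        scores = rng.random(300) + 0.5 * labels
        auc, aupr = evaluate(scores, labels)
        ci = bootstrap_ci(scores, labels, B=300, seed=0)
        assert ci["auc"][0] <= auc <= ci["auc"][1]
        assert ci["aupr"][0] <= aupr <= ci["aupr"][1]

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)
        widths = []
        for n in (100, 10000):
            diffs = []
            for seed in range(5):
                labels = (rng.random(n) < 0.3).astype(int)
                scores = rng.random(n) + 0.6 * labels
                ci = bootstrap_ci(scores, labels, B=200, seed=seed)
                diffs.append(ci["auc"][1] - ci["auc"][0])
            widths.append(np.mean(diffs))
        assert widths[1] < widths[0]

    def test_small_b_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([1.0, 0.0]), np.array([1, 0]), B=10)


@pytest.fixture(scope="module")
def small_problem():
    spec = SyntheticSpec(n_drug=40, n_protein=50, n_disease=10, n_se=10,
                         latent_rank=4, seed=0,
                         densities={"drug_protein": 0.08, "drug_drug": 0.1,
                                    "protein_protein": 0.1, "drug_disease": 0.1,
                                    "drug_se": 0.1, "protein_disease": 0.1})
    g, ft, _ = generate(spec)
    cfg = RunConfig(dim=16, proj_dim=8, epochs=30, patience=50, lam_l2=100.0,
                    feat_dropout=0.0, att_dropout=0.0, recon_on_sigmoid=False,
                    neg_excl_cutoff=0.0)
    pairs = labeled_pairs(g, cfg, seed=0)
    plan = make_split_plan(pairs, "standard", k=5, seed=0)
    return g, ft, cfg, plan


class TestTrainLoop:
    def test_learns_above_chance_on_planted_factors(self, small_problem):
        g, ft, cfg, plan = small_problem
        res = train(g, ft.tables, cfg, plan.folds[0], seed=0)
        assert res.val_auc > 0.5

    def test_forced_plateau_stops_after_patience(self, small_problem):
        g, ft, cfg, plan = small_problem
        cfg2 = cfg.replace(lr=0.0, epochs=100, patience=10)
        res = train(g, ft.tables, cfg2, plan.folds[0], seed=0)
        # epoch 1 sets the best; exactly `patience` stale epochs follow
        assert res.history[-1]["epoch"] == 1 + 10
        assert res.best_epoch == 1

    def test_same_seed_reproduces_first_epoch_loss(self, small_problem):
        g, ft, cfg, plan = small_problem
        cfg2 = cfg.replace(epochs=1)
        r1 = train(g, ft.tables, cfg2, plan.folds[0], seed=3)
        r2 = train(g, ft.tables, cfg2, plan.folds[0], seed=3)
        assert abs(r1.history[0]["L_total"] - r2.history[0]["L_total"]) < 1e-6

    def test_run_plan_report_structure(self, small_problem):
        g, ft, cfg, plan = small_problem
        cfg2 = cfg.replace(epochs=5)
        plan.folds = plan.folds[:2]
        rep = run_plan(g, ft.tables, cfg2, plan, seed=0, bootstrap=150)
        assert len(rep.fold_metrics) == 2
        assert 0 <= rep.mean_auc <= 1 and 0 <= rep.mean_aupr <= 1
        assert rep.ci["auc"][0] <= rep.ci["auc"][1]
        d = rep.to_dict()
        assert d["auc"]["ci95"] is not None
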