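"""Ranking metrics against brute-force oracles, protocol contracts,
PR curves and the paired Wilcoxon comparison."""

import numpy as np
import pytest
from scipy.stats import binomtest

from targetpath.errors import (InputError, UndefinedMetricError,
                               UndefinedTestError)
from targetpath.evaluation import (average_precision, compare_paired,
                                   evaluate, pr_curve, precision_at_k,
                                   quate_baseline, quate_score_fn,
                                   random_score_fn)
from targetpath.quate import QuatEConfig, train_quate
from targetpath.training import SplitConfig, split_edges


def _avep_oracle(ranked, relevant):
    """Straight per-position implementation of average precision."""
    relevant = set(relevant)
    precisions = []
    hits = 0
    for k, item in enumerate(ranked, 1):
        if item in relevant:
            hits += 1
            precisions.append(hits / k)
    return sum(precisions) / len(precisions)


def test_average_precision_examples():
    assert average_precision(["a", "b", "c"], {"a", "b"}) == 1.0
    # ranking (+, -, +, -) with 2 relevant: (1 + 2/3) / 2 = 5/6
    assert average_precision(["a", "x", "b", "y"], {"a", "b"}) == \
        pytest.approx(5 / 6)
    with pytest.raises(UndefinedMetricError):
        average_precision(["x", "y"], {"a"})


def test_average_precision_matches_oracle(rng):
    for _ in range(1000):
        n = int(rng.integers(3, 30))
        items = [f"i{j}" for j in range(n)]
        ranked = list(rng.permutation(items))
        relevant = set(rng.choice(items, size=int(rng.integers(1, n)),
                                  replace=False))
        assert average_precision(ranked, relevant) == \
            _avep_oracle(ranked, relevant)


def test_precision_at_k():
    ranked = [f"g{i}" for i in range(30)]
    assert precision_at_k(ranked, {f"g{i}" for i in range(5)}, 20) == 0.25
    assert precision_at_k(ranked, {"zz"}, 20) == 0.0
    assert precision_at_k(ranked, set(ranked[:20]), 20) == 1.0
    # denominator stays k with fewer candidates
    assert precision_at_k(["a", "b"], {"a", "b"}, 20) == 0.1


def test_evaluate_oracle_scorer_and_no_leakage(small_synthetic):
    kg, _ = small_synthetic
    split = split_edges(kg, SplitConfig(min_test=10, seed=2))
    relevant = split.test_genes

    def oracle(d, g):
        return 1.0 if g in relevant[d] else 0.0

    res = evaluate(oracle, kg, split, "all_association")
    assert (res.per_disease.avep == 1.0).all()
    # train positives are excluded from every candidate list
    train_genes = split.train_genes()
    for d in split.retained_diseases:
        n_cand = res.per_disease.set_index("disease").loc[d, "n_candidates"]
        assert n_cand == len(kg.nodes_of_type("GE")) - len(train_genes[d])


def test_evaluate_null_calibration(small_synthetic, rng):
    """Random scores give mean AveP matching an independent permutation
    oracle (and close to the prevalence of relevant among candidates,
    which it slightly exceeds in finite samples)."""
    kg, _ = small_synthetic
    split = split_edges(kg, SplitConfig(min_test=10, seed=2))
    n_ge = len(kg.nodes_of_type("GE"))
    train_genes = split.train_genes()
    # independent oracle: mean AveP of shuffled candidate lists
    per_disease = []
    for d in split.retained_diseases:
        cands = [g for g in kg.nodes_of_type("GE")
                 if g not in train_genes.get(d, set())]
        rel = split.test_genes[d]
        sims = [_avep_oracle(rng.permutation(cands), rel) for _ in range(60)]
        per_disease.append(np.mean(sims))
    expected = float(np.mean(per_disease))
    aveps = [evaluate(random_score_fn(s), kg, split,
                      "all_association").mean_avep for s in range(20)]
    se = np.std(aveps, ddof=1) / np.sqrt(len(aveps))
    assert abs(np.mean(aveps) - expected) < 3 * se + 0.005
    prev = np.mean([len(split.test_genes[d])
                    / (n_ge - len(train_genes.get(d, ())))
                    for d in split.retained_diseases])
    assert abs(np.mean(aveps) - prev) < 0.05


def test_causal_only_skips_diseases_without_causal_tests(small_synthetic):
    kg, _ = small_synthetic
    split = split_edges(kg, SplitConfig(min_test=10, seed=2))
    res = evaluate(random_score_fn(0), kg, split, "causal_only")
    with_causal = {d for d, genes in split.test_genes_causal().items()
                   if genes}
    assert set(res.per_disease.disease) == with_causal


def test_quate_baseline_interface(small_synthetic):
    kg, _ = small_synthetic
    split = split_edges(kg, SplitConfig(min_test=10, seed=2))
    emb = train_quate(kg.subgraph_without_edges(
        [(d, "asw", g) for d, g, _c in split.test_edges]),
        QuatEConfig(k=8, epochs=10, seed=0))
    d = split.retained_diseases[0]
    r1 = quate_baseline(emb, d, kg, split)
    r2 = quate_baseline(emb, d, kg, split)
    assert r1 == r2
    # evaluate() accepts the same scores unchanged
    res = evaluate(quate_score_fn(emb), kg, split, "all_association")
    assert res.per_disease.avep.between(0, 1).all()
    # trained baseline beats the random null on average
    null = np.mean([evaluate(random_score_fn(s), kg, split,
                             "all_association").mean_avep
                    for s in range(5)])
    assert res.mean_avep > null


def test_pr_curve_contracts():
    pts = pr_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert (1.0, 1.0) in pts
    recalls = [r for r, _p in pts]
    assert recalls == sorted(recalls)
    # all-equal scores collapse to a single point (1.0, prevalence)
    assert pr_curve([0.5] * 4, [1, 0, 0, 1]) == [(1.0, 0.5)]
    with pytest.raises(InputError):
        pr_curve([0.1, 0.2], [0, 0])


def test_pr_curve_matches_sklearn_oracle(rng):
    from sklearn.metrics import precision_recall_curve
    for _ in range(200):
        n = int(rng.integers(4, 40))
        scores = rng.normal(size=n)
        labels = rng.random(n) < 0.4
        if labels.sum() == 0:
            labels[0] = True
        mine = pr_curve(scores, labels)
        prec, rec, _thr = precision_recall_curve(labels, scores)
        ours = {(round(r, 12), round(p, 12)) for r, p in mine}
        theirs = {(round(r, 12), round(p, 12))
                  for p, r in zip(prec, rec) if r > 0}
        assert theirs <= ours | {(0.0, 1.0)} or ours == theirs
        # areas agree (trapezoid over the shared grid)
        area_mine = np.trapezoid([p for _r, p in mine],
                                 [r for r, _p in mine])
        area_skl = np.trapezoid(prec[::-1][1:], rec[::-1][1:]) \
            if len(prec) > 1 else 0.0
        assert area_mine == pytest.approx(area_skl, abs=1e-9)


def test_compare_paired():
    a = np.arange(10, dtype=float)
    p = compare_paired(a, a + 1.0)
    assert p == pytest.approx(1.0 / 2 ** 10)
    assert compare_paired(a, a - 1.0) > 0.99
    with pytest.raises(UndefinedTestError):
        compare_paired(a, a.copy())
    with pytest.raises(InputError):
        compare_paired([1.0, 2.0], [2.0, 3.0])


def test_compare_paired_null_calibration(rng):
    """Under symmetric differences the one-sided p-value is roughly
    uniform: its median over 200 replicates is near 0.5."""
    ps = []
    for _ in range(200):
        a = rng.normal(size=20)
        b = a + rng.normal(size=20)
        ps.append(compare_paired(a, b))
    assert 0.35 < np.median(ps) < 0.65
    assert binomtest(sum(p < 0.5 for p in ps), 200, 0.5).pvalue > 1e-4
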