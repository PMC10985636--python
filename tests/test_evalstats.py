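"""Statistics: AUC pair-count oracle, DeLong variance/calibration,
average precision, bootstrap, Dice, weighted kappa, subgroup tables."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from tpas.evalstats import (ScoredCohort, bootstrap_auprc_diff, delong_test,
                            delong_auc_variance, dice, lesion_pr_auprc,
                            roc_auc, subgroup_report, weighted_kappa)


def auc_pair_oracle(scores, labels):
    """Exact rational pair counting: P(s+ > s-) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = Fraction(0)
    for p in pos:
        for n in neg:
            if p > n:
                total += 1
            elif p == n:
                total += Fraction(1, 2)
    return float(total / (len(pos) * len(neg)))


def test_roc_auc_examples():
    assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
    assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5
    assert roc_auc([0.1, 0.4, 0.35, 0.8],
                   [0, 0, 1, 1]) == pytest.approx(0.75)
    with pytest.raises(ValueError):
        roc_auc([0.5, 0.6], [1, 1])


def test_roc_auc_equals_pair_counting_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(4, 60))
        scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n) \
            if rng.random() < 0.5 else rng.random(size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        assert roc_auc(scores, labels) == auc_pair_oracle(scores, labels)


def test_delong_identical_scorers():
    rng = np.random.default_rng(1)
    s = rng.random(40)
    labels = rng.integers(0, 2, size=40)
    labels[:2] = [0, 1]
    out = delong_test(s, s, labels)
    assert out["delta_auc"] == 0.0
    assert out["p"] == 1.0


def test_delong_variance_matches_jackknife():
    """DeLong's variance for a single AUC tracks the leave-one-out
    jackknife estimate on small random instances."""
    rng = np.random.default_rng(2)
    for _ in range(5):
        n = 40
        labels = np.array([0] * 20 + [1] * 20)
        scores = rng.random(n) + labels * 0.4
        auc, var = delong_auc_variance(scores, labels)
        # jackknife
        thetas = []
        for i in range(n):
            keep = np.arange(n) != i
            thetas.append(roc_auc(scores[keep], labels[keep]))
        thetas = np.asarray(thetas)
        jk = (n - 1) / n * ((thetas - thetas.mean()) ** 2).sum()
        assert var == pytest.approx(jk, rel=0.35, abs=2e-4)


def test_delong_p_agrees_with_permutation_oracle():
    """Two-sided DeLong p vs a paired sign-flip permutation oracle at n=40
    (the scorers' roles are exchanged per case)."""
    rng = np.random.default_rng(3)
    n = 40
    labels = np.array([0] * 20 + [1] * 20)
    base = rng.random(n) + labels * 0.6
    a = base + rng.normal(0, 0.25, n)
    b = base + rng.normal(0, 0.25, n)
    p_delong = delong_test(a, b, labels)["p"]
    observed = abs(roc_auc(a, labels) - roc_auc(b, labels))
    m = 10_000
    flips = rng.random((m, n)) < 0.5
    count = 0
    for f in flips:
        aa = np.where(f, b, a)
        bb = np.where(f, a, b)
        if abs(roc_auc(aa, labels) - roc_auc(bb, labels)) >= observed - 1e-12:
            count += 1
    p_perm = count / m
    assert p_delong == pytest.approx(p_perm, abs=0.06)


def _cohort(case_rows, cand_rows):
    cases = pd.DataFrame(case_rows, columns=["case_id", "score", "label",
                                             "grade", "site", "n_gt", "dice"])
    cands = pd.DataFrame(cand_rows, columns=["case_id", "cand_id",
                                             "probability", "volume",
                                             "centroid_z", "centroid_y",
                                             "centroid_x", "is_tp"])
    return ScoredCohort(cases, cands)


def ap_oracle(probs, is_tp, n_gt):
    order = np.argsort(-np.asarray(probs), kind="stable")
    tp = np.asarray(is_tp)[order]
    precisions = []
    seen_tp = 0
    for k, hit in enumerate(tp, start=1):
        if hit:
            seen_tp += 1
            precisions.append(seen_tp / k)
    return sum(precisions) / n_gt


def test_auprc_hand_example():
    """(TP, FP, TP) by rank with 2 gt lesions: AP = (1 + 2/3)/2 = 0.8333."""
    c = _cohort(
        [("a", 0.9, 1, 1, "s", 2, 0.5)],
        [("a", 0, 0.9, 5, 0, 0, 0, True),
         ("a", 1, 0.8, 5, 0, 0, 0, False),
         ("a", 2, 0.7, 5, 0, 0, 0, True)])
    assert lesion_pr_auprc(c) == pytest.approx(0.833333333, abs=1e-9)


def test_auprc_edge_cases():
    full = _cohort([("a", 0.9, 1, 1, "s", 1, 0.5)],
                   [("a", 0, 0.9, 5, 0, 0, 0, True)])
    assert lesion_pr_auprc(full) == 1.0
    empty = _cohort([("a", 0.0, 1, 1, "s", 1, 0.5)], [])
    assert lesion_pr_auprc(empty) == 0.0
    no_gt = _cohort([("a", 0.0, 0, 1, "s", 0, None)], [])
    with pytest.raises(ValueError):
        lesion_pr_auprc(no_gt)


def test_auprc_matches_bruteforce_on_random_cohorts():
    rng = np.random.default_rng(4)
    for _ in range(40):
        rows, cands = [], []
        n_gt_total = 0
        for ci in range(int(rng.integers(1, 5))):
            n_gt = int(rng.integers(0, 3))
            n_gt_total += n_gt
            rows.append((f"c{ci}", rng.random(), 1, 1, "s", n_gt, 0.5))
            n_tp = 0
            for k in range(int(rng.integers(0, 4))):
                is_tp = bool(rng.random() < 0.5) and n_tp < n_gt
                n_tp += is_tp
                cands.append((f"c{ci}", k, float(rng.random()), 3,
                              0, 0, 0, is_tp))
        if n_gt_total == 0:
            continue
        c = _cohort(rows, cands)
        probs = [r[2] for r in cands]
        tps = [r[7] for r in cands]
        assert lesion_pr_auprc(c) == pytest.approx(
            ap_oracle(probs, tps, n_gt_total), abs=1e-12)


def test_bootstrap_identical_cohorts_gives_p_one():
    c = _cohort(
        [("a", 0.9, 1, 1, "s", 1, 0.5), ("b", 0.2, 0, 1, "s", 1, 0.4)],
        [("a", 0, 0.9, 5, 0, 0, 0, True),
         ("b", 0, 0.3, 5, 0, 0, 0, False)])
    out = bootstrap_auprc_diff(c, c, b=200, seed=1)
    assert out["delta_auprc"] == 0.0
    assert out["p"] == 1.0
    assert out["ci"][0] <= 0.0 <= out["ci"][1]
    with pytest.raises(ValueError):
        bootstrap_auprc_diff(c, c, b=50, seed=1)


def test_bootstrap_ci_monotone_in_coverage_and_deterministic():
    rng = np.random.default_rng(5)
    rows_a, rows_b, cands_a, cands_b = [], [], [], []
    for ci in range(12):
        rows_a.append((f"c{ci}", rng.random(), 1, 1, "s", 1, 0.5))
        rows_b.append((f"c{ci}", rng.random(), 1, 1, "s", 1, 0.5))
        cands_a.append((f"c{ci}", 0, float(rng.random()), 3, 0, 0, 0,
                        bool(rng.random() < 0.7)))
        cands_b.append((f"c{ci}", 0, float(rng.random()), 3, 0, 0, 0,
                        bool(rng.random() < 0.4)))
    ca, cb = _cohort(rows_a, cands_a), _cohort(rows_b, cands_b)
    o90 = bootstrap_auprc_diff(ca, cb, b=300, seed=2, ci_level=0.90)
    o99 = bootstrap_auprc_diff(ca, cb, b=300, seed=2, ci_level=0.99)
    assert o99["ci"][0] <= o90["ci"][0] and o90["ci"][1] <= o99["ci"][1]
    again = bootstrap_auprc_diff(ca, cb, b=300, seed=2, ci_level=0.90)
    assert again == o90


def test_dice_closed_forms_and_symmetry():
    a = np.zeros((4, 4), dtype=bool)
    a[:2] = True
    assert dice(a, a) == 1.0
    b = ~a
    assert dice(a, b) == 0.0
    # |A|=4, |B|=4, |∩|=2 -> 0.5
    x = np.zeros(10, dtype=bool)
    y = np.zeros(10, dtype=bool)
    x[:4] = True
    y[2:6] = True
    assert dice(x, y) == 0.5 == dice(y, x)
    assert dice(np.zeros(3, bool), np.zeros(3, bool)) == 1.0
    with pytest.raises(ValueError):
        dice(np.zeros(3, bool), np.zeros(4, bool))


def test_weighted_kappa_closed_forms():
    r = [1, 2, 3, 4, 2, 3]
    assert weighted_kappa(r, r) == pytest.approx(1.0)
    # 2x2 hand computation: O = [[.25,.25],[.25,.25]] marginals .5/.5
    # linear weights w01=w10=1 -> 1 - .5/.5 = 0
    assert weighted_kappa([1, 1, 2, 2], [1, 2, 1, 2], k=2) == pytest.approx(0)
    with pytest.raises(ValueError):
        weighted_kappa([0, 1], [1, 1])


def test_weighted_kappa_near_zero_under_independence():
    rng = np.random.default_rng(6)
    r1 = np.full(2000, 2)
    r2 = rng.integers(1, 5, size=2000)
    assert abs(weighted_kappa(r1, r2)) < 0.05


def test_weighted_kappa_agrees_with_sklearn():
    sklearn = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(7)
    r1 = rng.integers(1, 5, size=300)
    r2 = np.clip(r1 + rng.integers(-1, 2, size=300), 1, 4)
    for ours, theirs in (("linear", "linear"), ("quadratic", "quadratic")):
        assert weighted_kappa(r1, r2, weights=ours) == pytest.approx(
            sklearn.cohen_kappa_score(r1, r2, weights=theirs), abs=1e-12)


def test_subgroup_report_partitions_and_consistency():
    rows = [("a", 0.9, 1, 1, "s1", 1, 0.5), ("b", 0.1, 0, 1, "s1", 0, None),
            ("c", 0.8, 1, 2, "s2", 1, 0.6), ("d", 0.3, 0, 2, "s2", 0, None),
            ("e", 0.7, 1, 2, "s2", 1, 0.7)]
    cands = [("a", 0, 0.9, 3, 0, 0, 0, True),
             ("c", 0, 0.8, 3, 0, 0, 0, True),
             ("e", 0, 0.7, 3, 0, 0, 0, False)]
    sc = _cohort(rows, cands)
    rep = subgroup_report(sc, by="grade")
    assert rep["n"].sum() == 5
    g2 = rep[rep["grade"] == 2].iloc[0]
    sub = sc.cases[sc.cases.grade == 2]
    assert g2["auc"] == pytest.approx(roc_auc(sub["score"], sub["label"]))
    single = subgroup_report(_cohort(rows[:2], cands[:1]), by="grade")
    assert len(single) == 1
    with pytest.raises(ValueError):
        subgroup_report(sc, by="age")


def test_subgroup_single_class_reported_as_na():
    rows = [("a", 0.9, 1, 1, "s1", 1, 0.5), ("b", 0.8, 1, 1, "s1", 1, 0.4)]
    sc = _cohort(rows, [])
    rep = subgroup_report(sc, by="grade")
    assert len(rep) == 1 and np.isnan(rep["auc"].iloc[0])
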