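"""The statistical toolbox on synthetic scores: correlated-AUC comparison
(DeLong), average precision, paired bootstrap, Dice and weighted kappa."""

import numpy as np

from tpas.evalstats import (bootstrap_auprc_diff, delong_test, dice,
                            lesion_pr_auprc, roc_auc, weighted_kappa,
                            ScoredCohort)
import pandas as pd

rng = np.random.default_rng(0)
n = 120
labels = rng.integers(0, 2, size=n)
signal = labels * 1.2 + rng.normal(size=n)
model_a = signal + rng.normal(0, 0.6, n)         # the better scorer
model_b = 0.7 * signal + rng.normal(0, 0.9, n)

print(f"AUC A = {roc_auc(model_a, labels):.3f}, "
      f"AUC B = {roc_auc(model_b, labels):.3f}")
d = delong_test(model_a, model_b, labels)
print(f"DeLong: dAUC = {d['delta_auc']:+.3f}, z = {d['z']:.2f}, "
      f"p = {d['p']:.4f}")

def toy_cohort(tp_rate, seed):
    r = np.random.default_rng(seed)
    cases, cands = [], []
    for ci in range(30):
        cases.append((f"c{ci}", r.random(), 1, 1, "s", 1, 0.5))
        cands.append((f"c{ci}", 0, float(r.random()), 3, 0, 0, 0,
                      bool(r.random() < tp_rate)))
    cols_cases = ["case_id", "score", "label", "grade", "site", "n_gt", "dice"]
    cols_cands = ["case_id", "cand_id", "probability", "volume",
                  "centroid_z", "centroid_y", "centroid_x", "is_tp"]
    return ScoredCohort(pd.DataFrame(cases, columns=cols_cases),
                        pd.DataFrame(cands, columns=cols_cands))

good, weak = toy_cohort(0.8, 1), toy_cohort(0.5, 2)
print(f"AUPRC good = {lesion_pr_auprc(good):.3f}, "
      f"weak = {lesion_pr_auprc(weak):.3f}")
b = bootstrap_auprc_diff(good, weak, b=500, seed=3)
print(f"bootstrap dAUPRC = {b['delta_auprc']:+.3f}, "
      f"95% CI ({b['ci'][0]:+.3f}, {b['ci'][1]:+.3f}), p = {b['p']:.3f}")

m1 = np.zeros((8, 8), dtype=bool); m1[2:6, 2:6] = True
m2 = np.zeros((8, 8), dtype=bool); m2[3:7, 2:6] = True
print(f"Dice of shifted squares = {dice(m1, m2):.3f}")

r1 = rng.integers(1, 5, size=200)
r2 = np.clip(r1 + rng.integers(-1, 2, size=200), 1, 4)
print(f"weighted kappa (near-agreeing readers) = "
      f"{weighted_kappa(r1, r2):.3f}")
# The DeLong p-value accounts for the correlation induced by scoring the
# same patients; the bootstrap resamples patients, keeping each patient's
# candidates together.
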