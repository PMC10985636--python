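"""Paired-model evaluation: ROC/AUC with the DeLong test, lesion-level
PR/AUPRC with bootstrap comparison, Dice, weighted kappa, and subgroup
tables.

Patient-level performance is the Mann-Whitney AUC of the patient csPCa
score; the correlated-AUC comparison uses DeLong's structural-components
variance estimate. Lesion-level performance pools candidates over the
cohort and computes average precision (step-wise interpolation) with the
recall denominator equal to the number of ground-truth csPCa lesions;
between-model AUPRC differences are assessed by paired patient-level
bootstrap resampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .model import TaskModel, predict_confidence
from .phantom import PhantomCase
from .postproc import (cspca_instances, extract_candidates, match_lesions,
                       patient_score)

__all__ = ["ScoredCohort", "EvalReport", "roc_auc", "delong_test",
           "lesion_pr_auprc", "bootstrap_auprc_diff", "dice",
           "weighted_kappa", "subgroup_report", "compare_models",
           "score_cohort", "delong_auc_variance"]


# -------------------------------------------------------------- ScoredCohort
@dataclass
class ScoredCohort:
    """Per-case scores, labels and matched candidates for one model on one
    cohort."""
    cases: pd.DataFrame          # case_id, score, label, grade, site, n_gt,
                                 # dice (NaN when no gt csPCa lesion)
    candidates: pd.DataFrame     # case_id, cand_id, probability, volume,
                                 # centroid_z/y/x, is_tp

    def validate(self) -> None:
        if not self.cases["score"].between(0, 1).all():
            raise ValueError("patient scores must be in [0, 1]")
        if not self.cases["label"].isin([0, 1]).all():
            raise ValueError("labels must be binary")
        tp_counts = (self.candidates.groupby("case_id")["is_tp"].sum()
                     if len(self.candidates) else pd.Series(dtype=float))
        for cid, ntp in tp_counts.items():
            n_gt = int(self.cases.loc[self.cases.case_id == cid,
                                      "n_gt"].iloc[0])
            if ntp > n_gt:
                raise ValueError(f"more TPs than gt lesions for {cid}")

    @property
    def n_gt_total(self) -> int:
        return int(self.cases["n_gt"].sum())


def score_cohort(model: TaskModel, cases: list[PhantomCase],
                 threshold: float = 0.45, min_size: int = 2,
                 min_overlap: float = 0.10) -> ScoredCohort:
    """Run the full per-case pipeline: confidence map -> candidates ->
    matching -> patient score; Dice of the thresholded map against the
    csPCa ground truth for positive cases."""
    case_rows, cand_rows = [], []
    for case in cases:
        conf = predict_confidence(model, case)
        cands = extract_candidates(conf, threshold, min_size)
        gt = cspca_instances(case)
        m = match_lesions(cands, gt, min_overlap)
        tp_set = {ci for ci, _, _ in m.tp}
        gt_any = bool((gt > 0).any())
        d = dice(conf >= threshold, gt > 0) if gt_any else np.nan
        case_rows.append({
            "case_id": case.case_id, "score": patient_score(cands),
            "label": int(case.patient_label), "grade": case.artifact.grade,
            "site": case.site_tag, "n_gt": int(len(np.unique(gt)) - 1),
            "dice": d})
        for k, c in enumerate(cands):
            cz, cy, cx = c.centroid
            cand_rows.append({
                "case_id": case.case_id, "cand_id": k,
                "probability": c.probability, "volume": c.volume,
                "centroid_z": cz, "centroid_y": cy, "centroid_x": cx,
                "is_tp": k in tp_set})
    cols = ["case_id", "cand_id", "probability", "volume", "centroid_z",
            "centroid_y", "centroid_x", "is_tp"]
    sc = ScoredCohort(pd.DataFrame(case_rows),
                      pd.DataFrame(cand_rows, columns=cols))
    sc.validate()
    return sc


# ----------------------------------------------------------------- ROC / AUC
def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score+ > score-) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("roc_auc requires both classes")
    ranks = sstats.rankdata(scores)
    # numerator equals wins + ties/2 exactly (midranks are exact halves)
    num = ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2.0
    return num / (len(pos) * len(neg))


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components via midranks."""
    pos, neg = scores[labels == 1], scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = sstats.rankdata(np.concatenate([pos, neg]))
    rp, rn = sstats.rankdata(pos), sstats.rankdata(neg)
    v10 = (all_r[:m] - rp) / n               # per positive case
    v01 = 1.0 - (all_r[m:] - rn) / m         # per negative case
    auc = v10.mean()
    return auc, v10, v01


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """(AUC, variance) for a single ROC curve by DeLong's estimator."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    auc, v10, v01 = _placements(scores, labels)
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    return float(auc), float(var)


def delong_test(scores_a, scores_b, labels) -> dict:
    """Two-sided DeLong test for paired (same-case) AUCs.

    Returns ``{"auc_a", "auc_b", "delta_auc", "z", "p"}``; with a
    degenerate variance the z and p are NaN (reported, not raised).
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("delong_test requires paired scores on the "
                         "same cases")
    auc_a, v10a, v01a = _placements(a, labels)
    auc_b, v10b, v01b = _placements(b, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0 or not np.isfinite(var):
        # identical scorers: no evidence of a difference
        return {"auc_a": float(auc_a), "auc_b": float(auc_b),
                "delta_auc": float(delta),
                "z": 0.0 if delta == 0 else float("nan"),
                "p": 1.0 if delta == 0 else float("nan")}
    z = delta / np.sqrt(var)
    p = 2.0 * sstats.norm.sf(abs(z))
    return {"auc_a": float(auc_a), "auc_b": float(auc_b),
            "delta_auc": float(delta), "z": float(z), "p": float(p)}


# ------------------------------------------------------------------- AUPRC
def _pooled_ap(probs: np.ndarray, is_tp: np.ndarray, n_gt: int,
               keys: tuple | None = None) -> float:
    """Average precision over pooled candidates with stable tie-breaking.

    AP = sum over TP ranks k of precision@k, divided by the ground-truth
    lesion count (step-wise interpolation).
    """
    if n_gt < 1:
        raise ValueError("AUPRC requires at least one gt csPCa lesion")
    if len(probs) == 0:
        return 0.0
    order = np.lexsort(keys + (-probs,)) if keys else np.argsort(
        -probs, kind="stable")
    tp_sorted = np.asarray(is_tp, dtype=bool)[order]
    cum_tp = np.cumsum(tp_sorted)
    ranks = np.arange(1, len(tp_sorted) + 1)
    return float((cum_tp[tp_sorted] / ranks[tp_sorted]).sum() / n_gt)


def lesion_pr_auprc(cohort: ScoredCohort) -> float:
    """Lesion-level AUPRC (average precision) over the pooled cohort."""
    n_gt = cohort.n_gt_total
    c = cohort.candidates
    if len(c) == 0:
        if n_gt < 1:
            raise ValueError("AUPRC requires at least one gt csPCa lesion")
        return 0.0
    # stable order: probability desc, then case_id, cand_id
    keys = (c["cand_id"].to_numpy(),
            c["case_id"].astype("category").cat.codes.to_numpy())
    return _pooled_ap(c["probability"].to_numpy(),
                      c["is_tp"].to_numpy(), n_gt, keys)


def bootstrap_auprc_diff(cohort_a: ScoredCohort, cohort_b: ScoredCohort,
                         b: int = 1000, seed: int = 0,
                         ci_level: float = 0.95) -> dict:
    """Paired patient-level bootstrap of the AUPRC difference (A - B).

    Patients are resampled with replacement; both models are evaluated on
    the same resample, keeping each patient's candidates together. Returns
    the observed difference, a percentile CI and a two-sided p-value from
    the bootstrap distribution.
    """
    if b < 100:
        raise ValueError("bootstrap requires B >= 100 resamples")
    ids_a = list(cohort_a.cases["case_id"])
    ids_b = list(cohort_b.cases["case_id"])
    if len(ids_a) != len(ids_b):
        raise ValueError("cohorts must cover the same case set")
    rng = np.random.default_rng(seed)
    n = len(ids_a)

    def per_case(cohort: ScoredCohort):
        out = {}
        cand_by = {cid: g for cid, g in
                   cohort.candidates.groupby("case_id")} if \
            len(cohort.candidates) else {}
        for _, row in cohort.cases.iterrows():
            g = cand_by.get(row.case_id)
            probs = g["probability"].to_numpy() if g is not None else \
                np.empty(0)
            tps = g["is_tp"].to_numpy() if g is not None else \
                np.empty(0, bool)
            out[row.case_id] = (probs, tps, int(row.n_gt))
        return out

    pa, pb = per_case(cohort_a), per_case(cohort_b)

    def ap_of(per, sel_ids):
        probs = np.concatenate([per[i][0] for i in sel_ids]) \
            if sel_ids else np.empty(0)
        tps = np.concatenate([per[i][1] for i in sel_ids]) \
            if sel_ids else np.empty(0, bool)
        n_gt = sum(per[i][2] for i in sel_ids)
        if n_gt < 1:
            return np.nan
        return _pooled_ap(probs.astype(float), tps.astype(bool), n_gt)

    observed = ap_of(pa, ids_a) - ap_of(pb, ids_b)
    diffs = np.empty(b)
    for i in range(b):
        sel = rng.integers(0, n, size=n)
        ids = [ids_a[j] for j in sel]
        ids_bb = [ids_b[j] for j in sel]
        diffs[i] = ap_of(pa, ids) - ap_of(pb, ids_bb)
    diffs = diffs[np.isfinite(diffs)]
    lo_q = (1 - ci_level) / 2
    ci = (float(np.quantile(diffs, lo_q)),
          float(np.quantile(diffs, 1 - lo_q)))
    frac_le = float(np.mean(diffs < 0) + 0.5 * np.mean(diffs == 0))
    p = float(min(1.0, 2.0 * min(frac_le, 1.0 - frac_le)))
    return {"delta_auprc": float(observed), "ci": ci, "p": p,
            "n_resamples": int(len(diffs))}


# ------------------------------------------------------------- Dice / kappa
def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); 1.0 when both masks
    are empty (degenerate case, flagged in reports)."""
    a = np.asarray(mask_a, dtype=bool)
    bm = np.asarray(mask_b, dtype=bool)
    if a.shape != bm.shape:
        raise ValueError("dice requires same-shape masks")
    denom = a.sum() + bm.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, bm).sum() / denom)


def weighted_kappa(ratings1, ratings2, k: int = 4,
                   weights: str = "linear") -> float:
    """Cohen weighted kappa on an ordinal 1..k scale.

    kappa = 1 - sum(W * O) / sum(W * E) with linear (default) or quadratic
    disagreement weights; O is the observed contingency table and E the
    chance-expected table from the marginals.
    """
    r1 = np.asarray(ratings1, dtype=int)
    r2 = np.asarray(ratings2, dtype=int)
    if r1.shape != r2.shape:
        raise ValueError("rating vectors must have equal length")
    if np.any((r1 < 1) | (r1 > k)) or np.any((r2 < 1) | (r2 > k)):
        raise ValueError(f"ratings must lie in 1..{k}")
    n = len(r1)
    obs = np.zeros((k, k))
    np.add.at(obs, (r1 - 1, r2 - 1), 1.0)
    obs /= n
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    i, j = np.indices((k, k))
    w = np.abs(i - j) / (k - 1) if weights == "linear" else \
        ((i - j) / (k - 1)) ** 2
    if weights not in ("linear", "quadratic"):
        raise ValueError("weights must be 'linear' or 'quadratic'")
    denom = (w * exp).sum()
    if denom == 0:
        return 1.0
    return float(1.0 - (w * obs).sum() / denom)


# ---------------------------------------------------------------- subgroups
def subgroup_report(cohort: ScoredCohort, by: str) -> pd.DataFrame:
    """Per-stratum AUC/AUPRC; single-class strata are reported as NA."""
    if by not in ("grade", "site"):
        raise ValueError(f"unknown stratification key {by!r}")
    rows = []
    for val, grp in cohort.cases.groupby(by):
        sub_cases = grp.reset_index(drop=True)
        sub_cands = cohort.candidates[
            cohort.candidates.case_id.isin(set(grp.case_id))] \
            if len(cohort.candidates) else cohort.candidates
        sub = ScoredCohort(sub_cases, sub_cands)
        if sub_cases.label.nunique() < 2:
            auc = np.nan
        else:
            auc = roc_auc(sub_cases.score, sub_cases.label)
        try:
            auprc = lesion_pr_auprc(sub)
        except ValueError:
            auprc = np.nan
        rows.append({by: val, "n": len(grp), "auc": auc, "auprc": auprc})
    return pd.DataFrame(rows)


# ------------------------------------------------------------ EvalReport
@dataclass
class EvalReport:
    """The headline paired comparison bundle (JSON/CSV serializable)."""
    summary: dict
    subgroups: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_json(self) -> str:
        def clean(o):
            if isinstance(o, dict):
                return {str(k): clean(v) for k, v in sorted(o.items())}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            if isinstance(o, (np.floating, float)):
                f = float(o)
                return None if not np.isfinite(f) else f
            if isinstance(o, (np.integer, int)):
                return int(o)
            return o
        payload = {"summary": clean(self.summary),
                   "subgroups": {k: clean(v.to_dict(orient="records"))
                                 for k, v in sorted(self.subgroups.items())}}
        return json.dumps(payload, indent=1, sort_keys=True)

    def write(self, directory) -> list:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = [d / "report.json"]
        (d / "report.json").write_text(self.to_json())
        for name, df in self.subgroups.items():
            p = d / f"subgroup_{name}.csv"
            df.to_csv(p, index=False)
            paths.append(p)
        return paths


def _cohort_metrics(sc: ScoredCohort) -> dict:
    d = sc.cases["dice"].dropna()
    return {
        "auc": roc_auc(sc.cases.score, sc.cases.label),
        "auprc": lesion_pr_auprc(sc),
        "dice_mean": float(d.mean()) if len(d) else None,
        "dice_sd": float(d.std(ddof=1)) if len(d) > 1 else None,
        "n_cases": int(len(sc.cases)),
        "n_gt_lesions": sc.n_gt_total,
    }


def compare_models(control_model: TaskModel, tpas_model: TaskModel,
                   clean_cases: list[PhantomCase],
                   attacked_cases: list[PhantomCase],
                   attacked_cases_tpas: list[PhantomCase] | None = None,
                   threshold: float = 0.45, min_overlap: float = 0.10,
                   min_size: int = 2, bootstrap_b: int = 1000,
                   seed: int = 0) -> EvalReport:
    """The headline experiment: clean vs attacked performance of the
    defended and undefended models, with DeLong and bootstrap contrasts.

    ``attacked_cases`` must be the perturbed twins of ``clean_cases`` in
    the same order (ids suffixed with ``*``). When ``attacked_cases_tpas``
    is given, each model is evaluated on the noise crafted against *it*
    (the per-model resilience protocol); otherwise both models share one
    attacked cohort.
    """
    attacked = {"control": attacked_cases,
                "tpas": attacked_cases_tpas or attacked_cases}
    for atk_cases in attacked.values():
        if len(clean_cases) != len(atk_cases):
            raise ValueError("clean and attacked cohorts must be paired")
        for c, a in zip(clean_cases, atk_cases):
            if a.case_id.rstrip("*") != c.case_id:
                raise ValueError(
                    f"cohort id mismatch: {c.case_id} vs {a.case_id}")
    sc = {}
    for mname, model in (("control", control_model), ("tpas", tpas_model)):
        for cname, cases in (("clean", clean_cases),
                             ("attacked", attacked[mname])):
            sc[(mname, cname)] = score_cohort(model, cases, threshold,
                                              min_size, min_overlap)
    summary: dict = {"threshold": threshold, "min_overlap": min_overlap}
    for key, cohort in sc.items():
        summary[f"{key[0]}_{key[1]}"] = _cohort_metrics(cohort)
    for mname in ("control", "tpas"):
        summary[f"{mname}_delta_auc"] = (
            summary[f"{mname}_attacked"]["auc"]
            - summary[f"{mname}_clean"]["auc"])
        summary[f"{mname}_delta_auprc"] = (
            summary[f"{mname}_attacked"]["auprc"]
            - summary[f"{mname}_clean"]["auprc"])
    labels = sc[("control", "clean")].cases.label.to_numpy()
    for cname in ("clean", "attacked"):
        a = sc[("tpas", cname)].cases.score.to_numpy()
        bscores = sc[("control", cname)].cases.score.to_numpy()
        summary[f"delong_{cname}"] = delong_test(a, bscores, labels)
        summary[f"bootstrap_auprc_{cname}"] = bootstrap_auprc_diff(
            sc[("tpas", cname)], sc[("control", cname)], bootstrap_b, seed)
    subgroups = {}
    for key, cohort in sc.items():
        for by in ("grade", "site"):
            subgroups[f"{key[0]}_{key[1]}_{by}"] = subgroup_report(cohort, by)
    return EvalReport(summary, subgroups)
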