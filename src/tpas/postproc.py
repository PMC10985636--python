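"""From confidence maps to lesion candidates and patient-level scores.

Candidates are face-connected components (6-connectivity in 3D, which
reduces to 4-connectivity for single-slice volumes) of the supra-threshold
confidence map; each candidate's detection probability is the maximum
confidence over its voxels. The patient-level csPCa score is the maximum
candidate probability. Candidate-to-ground-truth matching follows the
challenge-style hit criterion: a candidate counts as a true positive when
its overlap with a (csPCa) ground-truth lesion reaches the minimum overlap,
0.10 by default, with overlap measured as intersection-over-union
(configurable to intersection-over-ground-truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import PhantomCase

__all__ = ["LesionCandidate", "MatchResult", "extract_candidates",
           "patient_score", "match_lesions", "cspca_instances"]


@dataclass
class LesionCandidate:
    indices: np.ndarray            # flat voxel indices into the map
    probability: float             # max confidence over the component
    centroid: tuple[float, ...]    # voxel coordinates (z, y, x)
    volume: int                    # voxel count

    def mask(self, shape: tuple[int, ...]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m.ravel()[self.indices] = True
        return m


@dataclass
class MatchResult:
    tp: list[tuple[int, int, float]]   # (candidate index, gt id, overlap)
    fp: list[int]                      # candidate indices
    fn: list[int]                      # unmatched gt lesion ids

    @property
    def n_tp(self) -> int:
        return len(self.tp)


def extract_candidates(conf_map: np.ndarray, threshold: float = 0.45,
                       min_size: int = 1) -> list[LesionCandidate]:
    """Connected components of {confidence >= threshold}, size-filtered and
    sorted by descending probability (stable; ties broken by first voxel
    index)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    conf = np.asarray(conf_map)
    structure = ndimage.generate_binary_structure(conf.ndim, 1)
    labels, n = ndimage.label(conf >= threshold, structure=structure)
    cands = []
    for lab in range(1, n + 1):
        comp = labels == lab
        size = int(comp.sum())
        if size < min_size:
            continue
        idx = np.flatnonzero(comp.ravel())
        centroid = tuple(float(v) for v in
                         np.mean(np.argwhere(comp), axis=0))
        cands.append(LesionCandidate(idx, float(conf.ravel()[idx].max()),
                                     centroid, size))
    cands.sort(key=lambda c: (-c.probability, int(c.indices[0])))
    return cands


def patient_score(candidates: list[LesionCandidate]) -> float:
    """Patient-level csPCa score: the top candidate probability, 0 if none."""
    return max((c.probability for c in candidates), default=0.0)


def cspca_instances(case: PhantomCase) -> np.ndarray:
    """Ground-truth instance mask restricted to csPCa lesions."""
    ids = [i for i, l in case.masks.lesion_labels.items() if l == "csPCa"]
    out = np.where(np.isin(case.masks.lesions, ids), case.masks.lesions, 0)
    return out.astype(np.int32)


def _overlap(cand_idx: np.ndarray, gt_idx: np.ndarray,
             criterion: str) -> float:
    inter = np.intersect1d(cand_idx, gt_idx, assume_unique=True).size
    if criterion == "iou":
        union = cand_idx.size + gt_idx.size - inter
        return inter / union if union else 0.0
    if criterion == "gt_fraction":
        return inter / gt_idx.size if gt_idx.size else 0.0
    raise ValueError(f"unknown overlap criterion {criterion!r}")


def match_lesions(candidates: list[LesionCandidate], gt_instances: np.ndarray,
                  min_overlap: float = 0.10,
                  criterion: str = "iou") -> MatchResult:
    """Greedy matching in descending candidate probability.

    ``gt_instances`` is an integer instance mask of the csPCa ground-truth
    lesions (0 = background). Each ground-truth lesion is matched at most
    once; a candidate is a true positive iff its best-overlap unmatched
    lesion reaches ``min_overlap``.
    """
    if not 0.0 < min_overlap <= 1.0:
        raise ValueError("min_overlap must be in (0, 1]")
    gt = np.asarray(gt_instances)
    if not np.issubdtype(gt.dtype, np.integer):
        raise ValueError("gt_instances must be an integer instance mask")
    gt_ids = sorted(int(i) for i in np.unique(gt) if i != 0)
    gt_idx = {i: np.flatnonzero(gt.ravel() == i) for i in gt_ids}
    unmatched = set(gt_ids)
    tp, fp = [], []
    order = sorted(range(len(candidates)),
                   key=lambda i: (-candidates[i].probability, i))
    for ci in order:
        cand = candidates[ci]
        best_id, best_ov = None, 0.0
        for gid in sorted(unmatched):
            ov = _overlap(cand.indices, gt_idx[gid], criterion)
            if ov > best_ov:
                best_id, best_ov = gid, ov
        if best_id is not None and best_ov >= min_overlap:
            tp.append((ci, best_id, best_ov))
            unmatched.discard(best_id)
        else:
            fp.append(ci)
    return MatchResult(tp, fp, sorted(unmatched))
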