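"""Recovery metrics against simulator ground truth.

Matches segmented nuclei to the cells the simulator placed (greedy
nearest-centroid with a distance cutoff) and scores detection and
classification. Evaluation is restricted to an interior region so that
cells clipped at the stack border — ambiguous for any counting rule — do
not contaminate the scores.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["match_cells", "detection_scores", "classification_scores"]


def match_cells(gt_centers: np.ndarray, seg_centers: np.ndarray,
                max_dist_um: float = 5.0):
    """Greedy one-to-one matching of ground-truth and segmented centroids.

    Candidate pairs within ``max_dist_um`` are taken in order of distance;
    each side is used at most once. Returns ``(pairs, dists)`` where pairs
    is an (m, 2) array of (gt_index, seg_index).
    """
    if len(gt_centers) == 0 or len(seg_centers) == 0:
        return np.empty((0, 2), dtype=int), np.empty(0)
    tree = cKDTree(seg_centers)
    cand = []
    for i, p in enumerate(gt_centers):
        for j in tree.query_ball_point(p, max_dist_um):
            d = float(np.linalg.norm(p - seg_centers[j]))
            cand.append((d, i, j))
    cand.sort()
    used_gt, used_seg = set(), set()
    pairs, dists = [], []
    for d, i, j in cand:
        if i in used_gt or j in used_seg:
            continue
        used_gt.add(i)
        used_seg.add(j)
        pairs.append((i, j))
        dists.append(d)
    return np.asarray(pairs, dtype=int).reshape(-1, 2), np.asarray(dists)


def _in_region(points, region):
    lo, hi = region
    points = np.asarray(points)
    return np.all(points >= np.asarray(lo), axis=1) & np.all(
        points <= np.asarray(hi), axis=1)


def detection_scores(gt_cells, nuclei, region, max_dist_um: float = 5.0):
    """Detection recall / precision / centroid error inside ``region``.

    Recall: fraction of ground-truth cells centered in the region matched
    by any segmented nucleus. Precision: fraction of segmented nuclei
    centered in the region matched by any ground-truth cell. The matching
    itself uses all objects so region-border pairs still find each other.
    """
    gt_centers = np.array([c.center_um for c in gt_cells]).reshape(-1, 3)
    seg_centers = np.array([n.centroid_um for n in nuclei]).reshape(-1, 3)
    pairs, dists = match_cells(gt_centers, seg_centers, max_dist_um)
    gt_matched = np.zeros(len(gt_cells), dtype=bool)
    seg_matched = np.zeros(len(nuclei), dtype=bool)
    if len(pairs):
        gt_matched[pairs[:, 0]] = True
        seg_matched[pairs[:, 1]] = True
    gt_in = _in_region(gt_centers, region) if len(gt_centers) else np.zeros(0, bool)
    seg_in = _in_region(seg_centers, region) if len(seg_centers) else np.zeros(0, bool)
    recall = float(gt_matched[gt_in].mean()) if gt_in.any() else np.nan
    precision = float(seg_matched[seg_in].mean()) if seg_in.any() else np.nan
    if len(pairs):
        pair_in = gt_in[pairs[:, 0]]
        med_err = float(np.median(dists[pair_in])) if pair_in.any() else np.nan
    else:
        med_err = np.nan
    return {"recall": recall, "precision": precision,
            "median_centroid_error_um": med_err,
            "n_gt": int(gt_in.sum()), "n_seg": int(seg_in.sum()),
            "pairs": pairs, "dists": dists}


def classification_scores(gt_cells, classified, region,
                          max_dist_um: float = 5.0):
    """Per-class precision/recall/F1 of recovered classes inside ``region``.

    ``classified`` is the list of ClassifiedCell for the segmented nuclei;
    classes are compared on matched (ground truth, nucleus) pairs.
    """
    gt_centers = np.array([c.center_um for c in gt_cells]).reshape(-1, 3)
    seg_centers = np.array(
        [c.nucleus.centroid_um for c in classified]).reshape(-1, 3)
    pairs, _ = match_cells(gt_centers, seg_centers, max_dist_um)
    gt_in = _in_region(gt_centers, region) if len(gt_centers) else np.zeros(0, bool)
    classes = ("neuron", "glia", "vascular")
    conf = {g: {p: 0 for p in classes} for g in classes}
    for i, j in pairs:
        if not gt_in[i]:
            continue
        conf[gt_cells[i].cell_class][classified[j].cell_class] += 1
    scores = {}
    for cls in classes:
        tp = conf[cls][cls]
        fn = sum(conf[cls][p] for p in classes) - tp
        fp = sum(conf[g][cls] for g in classes) - tp
        prec = tp / (tp + fp) if tp + fp else np.nan
        rec = tp / (tp + fn) if tp + fn else np.nan
        f1 = (2 * prec * rec / (prec + rec)
              if np.isfinite(prec) and np.isfinite(rec) and prec + rec else np.nan)
        scores[cls] = {"precision": prec, "recall": rec, "f1": f1,
                       "support": tp + fn}
    return {"per_class": scores, "confusion": conf}
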