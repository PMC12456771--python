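"""Scoring helpers against generator ground truth.

Point-level stem F1 and leaf-instance precision/recall under mutual-majority
matching (a predicted instance and a true leaf match iff their intersection
covers more than half of each).
"""

from __future__ import annotations

import numpy as np

__all__ = ["stem_f1", "instance_precision_recall", "trait_errors"]


def stem_f1(pred_stem_mask: np.ndarray, true_labels: np.ndarray) -> float:
    """F1 of the stem/non-stem decision; outlier points (-1) are ignored."""
    pred = np.asarray(pred_stem_mask, bool)
    true = np.asarray(true_labels)
    valid = true != -1
    tp = np.sum(pred & (true == 0) & valid)
    fp = np.sum(pred & (true != 0) & valid)
    fn = np.sum(~pred & (true == 0) & valid)
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else 0.0


def instance_precision_recall(
    pred_labels: np.ndarray, true_labels: np.ndarray
) -> tuple[float, float]:
    """(precision, recall) of leaf instances by mutual-majority overlap.

    ``pred_labels``: -1 for non-leaf points, 0..m-1 instances.
    ``true_labels``: 0 stem, 1..n true leaves, -1 outliers.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    pred_ids = [p for p in np.unique(pred) if p >= 0]
    true_ids = [t for t in np.unique(true) if t >= 1]
    matched = 0
    for p in pred_ids:
        pm = pred == p
        if not pm.any():
            continue
        overlap_best, best_t = 0, None
        for t in true_ids:
            ov = int(np.sum(pm & (true == t)))
            if ov > overlap_best:
                overlap_best, best_t = ov, t
        if best_t is None:
            continue
        tm = true == best_t
        if overlap_best > 0.5 * pm.sum() and overlap_best > 0.5 * tm.sum():
            matched += 1
    precision = matched / len(pred_ids) if pred_ids else 0.0
    recall = matched / len(true_ids) if true_ids else 0.0
    return float(precision), float(recall)


def matched_leaf_area_errors(
    pred_labels: np.ndarray,
    true_labels: np.ndarray,
    pred_areas: np.ndarray,
    true_areas: np.ndarray,
) -> list[float]:
    """|relative area error| per true leaf, matched by maximum point overlap.

    True leaves with no overlapping predicted instance are skipped (they are
    a recall failure, scored separately).
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    errs = []
    for t in range(1, int(true.max()) + 1 if len(true) else 0):
        tm = true == t
        if not tm.any():
            continue
        overlaps = [int(np.sum(tm & (pred == p))) for p in range(len(pred_areas))]
        if not overlaps or max(overlaps) == 0:
            continue
        p = int(np.argmax(overlaps))
        ta = float(true_areas[t - 1])
        errs.append(abs(float(pred_areas[p]) - ta) / ta)
    return errs


def trait_errors(report, truth, pred_labels=None, true_labels=None) -> dict:
    """Relative trait errors of a pipeline report vs generator ground truth.

    With per-point labels, leaf areas are compared between overlap-matched
    instance pairs; otherwise after sorting (descending) and truncating to
    the common count.
    """
    out = {
        "height_rel_err": abs(report.height - truth.true_height) / truth.true_height,
        "stem_length_rel_err": abs(report.stem_length - truth.true_stem_length)
        / truth.true_stem_length,
        "stem_diameter_rel_err": abs(report.stem_diameter - truth.true_stem_diameter)
        / truth.true_stem_diameter,
    }
    if pred_labels is not None and true_labels is not None:
        errs = matched_leaf_area_errors(
            pred_labels, true_labels, report.leaf_areas, truth.true_leaf_areas
        )
        out["leaf_area_mean_abs_rel_err"] = float(np.mean(errs)) if errs else float("nan")
        return out
    pred_a = np.sort(np.asarray(report.leaf_areas, float))[::-1]
    true_a = np.sort(np.asarray(truth.true_leaf_areas, float))[::-1]
    m = min(len(pred_a), len(true_a))
    if m:
        out["leaf_area_mean_abs_rel_err"] = float(
            np.mean(np.abs(pred_a[:m] - true_a[:m]) / true_a[:m])
        )
    else:
        out["leaf_area_mean_abs_rel_err"] = float("nan")
    return out
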