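"""Detection evaluation: precision / recall / mAP@0.5, confusion matrix,
and TIDE-style error decomposition.

Data model (array-based, one entry per image):

* predictions — ``dict[image_id -> (N, 6) array]`` with rows
  ``x1, y1, x2, y2, confidence, class_id``;
* ground truth — ``dict[image_id -> (M, 5) array]`` with rows
  ``x1, y1, x2, y2, class_id``.

Matching is the standard protocol: predictions ranked by confidence,
a prediction is a true positive when it overlaps a not-yet-matched
ground-truth box of the same class with IoU >= the threshold.  AP is
all-point (precision-envelope) integration of the PR curve; mAP averages
AP over the classes present in the ground truth.  The headline precision /
recall pair is taken at the confidence that maximizes F1 (reported in the
result).  Percentages throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EvalResult",
    "ErrorDecomposition",
    "pairwise_iou",
    "average_precision",
    "evaluate_detections",
    "decompose_errors",
]


def pairwise_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU matrix between (N, 4) and (M, 4) corner-form boxes."""
    a = np.asarray(a, float).reshape(-1, 4)
    b = np.asarray(b, float).reshape(-1, 4)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


@dataclass
class EvalResult:
    precision: float  # % at the max-F1 confidence
    recall: float  # %
    precision_all: float  # % over every prediction (TP/(TP+FP))
    recall_all: float  # % over every prediction (TP/(TP+FN))
    f1_confidence: float
    per_class_ap: dict  # class_id -> AP in %
    map50: float  # %
    confusion_matrix: np.ndarray  # (C+1, C+1); last row/col = background
    confusion_confidence: float
    n_predictions: int
    n_ground_truth: int


@dataclass
class ErrorDecomposition:
    """The six error counters.

    ``e_fp = e_cls + e_loc + e_bkg + e_dup`` and ``e_fn = e_miss +
    (ground truth lost to classification/localization confusions)`` hold
    exactly by construction.  ``rates`` normalizes FP-side counters by the
    number of predictions and FN-side counters by the number of ground
    truths.  ``delta_map`` is a ΔmAP-style estimate: the change in mAP@0.5
    when the offending predictions (or missed ground truths) are removed —
    an estimate in the spirit of detection-error toolkits, not their exact
    oracle.
    """

    e_cls: int
    e_loc: int
    e_bkg: int
    e_dup: int
    e_miss: int
    e_fp: int
    e_fn: int
    n_predictions: int
    n_ground_truth: int
    rates: dict = field(default_factory=dict)
    delta_map: dict = field(default_factory=dict)


def _ranked_matches(preds: dict, gts: dict, iou_thr: float):
    """Global confidence-ranked matching.

    Returns (conf, tp_flag, pred_cls) arrays over all predictions plus the
    per-class GT counts.  Each GT is matched at most once.
    """
    rows = []  # (conf, tp, cls)
    gt_counts: dict = {}
    for img, g in gts.items():
        g = np.asarray(g, float).reshape(-1, 5)
        for c in g[:, 4].astype(int):
            gt_counts[int(c)] = gt_counts.get(int(c), 0) + 1
    for img in sorted(set(preds) | set(gts)):
        p = np.asarray(preds.get(img, np.zeros((0, 6))), float).reshape(-1, 6)
        g = np.asarray(gts.get(img, np.zeros((0, 5))), float).reshape(-1, 5)
        if len(p) == 0:
            continue
        order = np.argsort(-p[:, 4], kind="stable")
        p = p[order]
        matched = np.zeros(len(g), bool)
        iou = pairwise_iou(p[:, :4], g[:, :4]) if len(g) else np.zeros((len(p), 0))
        for i in range(len(p)):
            tp = 0
            cand = np.where(
                (~matched)
                & (iou[i] >= iou_thr)
                & (g[:, 4].astype(int) == int(p[i, 5]))
            )[0]
            if len(cand):
                j = cand[np.argmax(iou[i, cand])]
                matched[j] = True
                tp = 1
            rows.append((p[i, 4], tp, int(p[i, 5])))
    if rows:
        arr = np.array(rows, float)
        order = np.argsort(-arr[:, 0], kind="stable")
        arr = arr[order]
        return arr[:, 0], arr[:, 1].astype(int), arr[:, 2].astype(int), gt_counts
    return np.zeros(0), np.zeros(0, int), np.zeros(0, int), gt_counts


def average_precision(tp: np.ndarray, n_gt: int) -> float:
    """All-point AP from a confidence-ranked TP/FP flag vector (fraction)."""
    if n_gt == 0:
        return float("nan")
    if len(tp) == 0:
        return 0.0
    tpc = np.cumsum(tp)
    fpc = np.cumsum(1 - tp)
    recall = tpc / n_gt
    precision = tpc / (tpc + fpc)
    mrec = np.concatenate(([0.0], recall, [recall[-1]]))
    mpre = np.concatenate(([1.0], precision, [0.0]))
    mpre = np.flip(np.maximum.accumulate(np.flip(mpre)))  # precision envelope
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def evaluate_detections(
    preds: dict,
    gts: dict,
    iou_thr: float = 0.5,
    confusion_conf: float = 0.25,
) -> EvalResult:
    """Evaluate a prediction set against ground truth at one IoU threshold.

    With no ground truth and no predictions at all, metrics are vacuously
    perfect (there was nothing to find and nothing was hallucinated).
    """
    conf, tp, cls, gt_counts = _ranked_matches(preds, gts, iou_thr)
    n_gt_total = sum(gt_counts.values())
    classes = sorted(gt_counts)

    per_class_ap = {}
    for c in classes:
        mask = cls == c
        per_class_ap[c] = 100.0 * average_precision(tp[mask], gt_counts[c])
    if per_class_ap:
        map50 = float(np.mean(list(per_class_ap.values())))
    else:
        map50 = 100.0 if len(conf) == 0 else 0.0

    # max-F1 operating point on the ranked arrays
    if len(conf):
        tpc = np.cumsum(tp)
        fpc = np.cumsum(1 - tp)
        prec = tpc / (tpc + fpc)
        rec = tpc / max(n_gt_total, 1)
        f1 = 2 * prec * rec / np.maximum(prec + rec, 1e-12)
        k = int(np.argmax(f1))
        precision, recall, f1_conf = 100 * prec[k], 100 * rec[k], float(conf[k])
        precision_all, recall_all = 100 * prec[-1], 100 * rec[-1]
    elif n_gt_total == 0:
        precision, recall, f1_conf = 100.0, 100.0, 1.0
        precision_all, recall_all = 100.0, 100.0
    else:
        precision, recall, f1_conf = 0.0, 0.0, 1.0
        precision_all, recall_all = 0.0, 0.0

    cm = _confusion_matrix(preds, gts, iou_thr, confusion_conf)
    return EvalResult(
        precision=float(precision),
        recall=float(recall),
        precision_all=float(precision_all),
        recall_all=float(recall_all),
        f1_confidence=f1_conf,
        per_class_ap=per_class_ap,
        map50=map50,
        confusion_matrix=cm,
        confusion_confidence=confusion_conf,
        n_predictions=int(len(conf)),
        n_ground_truth=int(n_gt_total),
    )


def _confusion_matrix(preds, gts, iou_thr, conf_thr):
    n_cls = 0
    for g in gts.values():
        g = np.asarray(g, float).reshape(-1, 5)
        if len(g):
            n_cls = max(n_cls, int(g[:, 4].max()) + 1)
    for p in preds.values():
        p = np.asarray(p, float).reshape(-1, 6)
        if len(p):
            n_cls = max(n_cls, int(p[:, 5].max()) + 1)
    cm = np.zeros((n_cls + 1, n_cls + 1), int)  # rows: predicted, cols: truth
    for img in sorted(set(preds) | set(gts)):
        p = np.asarray(preds.get(img, np.zeros((0, 6))), float).reshape(-1, 6)
        g = np.asarray(gts.get(img, np.zeros((0, 5))), float).reshape(-1, 5)
        p = p[p[:, 4] >= conf_thr]
        p = p[np.argsort(-p[:, 4], kind="stable")]
        matched = np.zeros(len(g), bool)
        iou = pairwise_iou(p[:, :4], g[:, :4]) if len(g) else np.zeros((len(p), 0))
        for i in range(len(p)):
            cand = np.where((~matched) & (iou[i] >= iou_thr))[0]
            if len(cand):
                j = cand[np.argmax(iou[i, cand])]
                matched[j] = True
                cm[int(p[i, 5]), int(g[j, 4])] += 1
            else:
                cm[int(p[i, 5]), n_cls] += 1  # background false positive
        for j in np.where(~matched)[0]:
            cm[n_cls, int(g[j, 4])] += 1  # missed ground truth
    return cm


def decompose_errors(
    preds: dict,
    gts: dict,
    tf: float = 0.5,
    tb: float = 0.1,
    with_delta_map: bool = True,
) -> ErrorDecomposition:
    """Partition detection errors into the six-counter taxonomy.

    After standard matching at the foreground threshold ``tf``, each false
    positive falls into exactly one bucket, checked in priority order:

    1. *duplicate* — best same-class GT IoU >= tf (that GT is already
       claimed by a higher-confidence detection);
    2. *classification* (``e_cls``) — IoU >= tf with a GT of another class;
    3. *localization* (``e_loc``) — same class, tb <= IoU < tf;
    4. *background* (``e_bkg``) — everything else (max IoU over GT < tb,
       plus the rare wrong-class medium-IoU case, folded in here so the
       accounting identity stays exact).

    ``e_miss`` counts GT with no prediction above ``tb`` IoU of any class;
    ``e_fn`` counts all unmatched GT.
    """
    e_cls = e_loc = e_bkg = e_dup = e_miss = e_fn = 0
    n_pred = n_gt = n_tp = 0
    bucket_preds: dict = {"cls": [], "loc": [], "bkg": [], "dup": []}
    missed_gt: list = []

    for img in sorted(set(preds) | set(gts)):
        p = np.asarray(preds.get(img, np.zeros((0, 6))), float).reshape(-1, 6)
        g = np.asarray(gts.get(img, np.zeros((0, 5))), float).reshape(-1, 5)
        n_pred += len(p)
        n_gt += len(g)
        order = np.argsort(-p[:, 4], kind="stable")
        p = p[order]
        iou = pairwise_iou(p[:, :4], g[:, :4]) if len(g) else np.zeros((len(p), 0))
        same = (p[:, 5:6].astype(int) == g[None, :, 4].astype(int)) if len(g) else np.zeros((len(p), 0), bool)
        matched = np.zeros(len(g), bool)
        is_tp = np.zeros(len(p), bool)
        for i in range(len(p)):
            cand = np.where((~matched) & (iou[i] >= tf) & same[i])[0]
            if len(cand):
                j = cand[np.argmax(iou[i, cand])]
                matched[j] = True
                is_tp[i] = True
        n_tp += int(is_tp.sum())
        for i in np.where(~is_tp)[0]:
            iou_same = iou[i][same[i]].max() if same[i].any() else 0.0
            iou_other = iou[i][~same[i]].max() if (~same[i]).any() and len(g) else 0.0
            if iou_same >= tf:
                e_dup += 1
                bucket_preds["dup"].append((img, order[i]))
            elif iou_other >= tf:
                e_cls += 1
                bucket_preds["cls"].append((img, order[i]))
            elif iou_same >= tb:
                e_loc += 1
                bucket_preds["loc"].append((img, order[i]))
            else:
                e_bkg += 1
                bucket_preds["bkg"].append((img, order[i]))
        for j in np.where(~matched)[0]:
            e_fn += 1
            if len(p) == 0 or iou[:, j].max() < tb:
                e_miss += 1
                missed_gt.append((img, j))

    e_fp = n_pred - n_tp
    assert e_fp == e_cls + e_loc + e_bkg + e_dup

    rates = {
        "e_cls": e_cls / max(n_pred, 1),
        "e_loc": e_loc / max(n_pred, 1),
        "e_bkg": e_bkg / max(n_pred, 1),
        "e_dup": e_dup / max(n_pred, 1),
        "e_miss": e_miss / max(n_gt, 1),
        "e_fp": e_fp / max(n_pred, 1),
        "e_fn": e_fn / max(n_gt, 1),
    }

    delta_map: dict = {}
    if with_delta_map:
        base = evaluate_detections(preds, gts, iou_thr=tf).map50
        for kind in ("cls", "loc", "bkg", "dup"):
            drop = set(bucket_preds[kind])
            fixed = {
                img: np.asarray(p, float).reshape(-1, 6)[
                    [k for k in range(len(np.asarray(p).reshape(-1, 6))) if (img, k) not in drop]
                ]
                for img, p in preds.items()
            }
            delta_map[f"e_{kind}"] = evaluate_detections(fixed, gts, iou_thr=tf).map50 - base
        miss = set(missed_gt)
        fixed_gts = {
            img: np.asarray(g, float).reshape(-1, 5)[
                [j for j in range(len(np.asarray(g).reshape(-1, 5))) if (img, j) not in miss]
            ]
            for img, g in gts.items()
        }
        delta_map["e_miss"] = evaluate_detections(preds, fixed_gts, iou_thr=tf).map50 - base

    return ErrorDecomposition(
        e_cls=e_cls, e_loc=e_loc, e_bkg=e_bkg, e_dup=e_dup, e_miss=e_miss,
        e_fp=e_fp, e_fn=e_fn, n_predictions=n_pred, n_ground_truth=n_gt,
        rates=rates, delta_map=delta_map,
    )
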