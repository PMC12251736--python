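"""Composite detection loss: box (MPDIoU or CIoU) + classification BCE +
distribution-focal term, with a simplified center-prior / top-k assigner.

The box term delegates to :mod:`leafdet.boxes` — the identical formulas run
on autodiff tensors here and on plain arrays in the scalar API, so a single
assigned pair reproduces the scalar worked examples exactly.  The assigner
is deliberately plain plumbing (anchor centers inside the ground-truth box,
top-k by decoded IoU, conflicts to the higher IoU, nearest-anchor fallback
for boxes smaller than a grid cell); the loss composition weights follow
the YOLOv8 convention (box 7.5, cls 0.5, dfl 1.5) and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import boxes as B
from .nn.autograd import Tensor, concat, no_grad
from .model import DetectionModel, ModelConfig

__all__ = ["LossBreakdown", "make_anchors", "decode_boxes", "compute_detection_loss"]


@dataclass
class LossBreakdown:
    box_loss: float
    cls_loss: float
    dfl_loss: float
    total: float
    num_assigned: int


def make_anchors(input_size: int, strides=(8, 16, 32)):
    """Anchor centers (A, 2) in input pixels plus per-anchor stride (A,)."""
    pts, strs = [], []
    for s in strides:
        n = input_size // s
        xs = (np.arange(n) + 0.5) * s
        gx, gy = np.meshgrid(xs, xs)
        pts.append(np.stack([gx.ravel(), gy.ravel()], axis=1))
        strs.append(np.full(n * n, s, float))
    return np.concatenate(pts), np.concatenate(strs)


def _flatten_head(outputs, reg_max: int, nc: int):
    """Per-level (box, cls) maps -> (N, A, 4, reg_max) and (N, A, nc)."""
    regs, clss = [], []
    for reg, cls in outputs:
        n, _, h, w = reg.shape
        regs.append(reg.reshape(n, 4, reg_max, h * w).transpose(0, 3, 1, 2))
        clss.append(cls.reshape(n, nc, h * w).transpose(0, 2, 1))
    return concat(regs, axis=1), concat(clss, axis=1)


def decode_boxes(reg: Tensor, anchors: np.ndarray, strides: np.ndarray) -> Tensor:
    """Distribution logits (N, A, 4, reg_max) -> corner boxes (N, A, 4) px.

    Softmax expectation over the bins gives the left/top/right/bottom
    distances in stride units (distribution-focal decoding).
    """
    reg_max = reg.shape[-1]
    proj = np.arange(reg_max, dtype=np.float32)
    dist = (reg.softmax(axis=-1) * proj).sum(axis=-1)  # (N, A, 4) ltrb
    sd = strides[None, :, None]
    ax = anchors[None, :, 0]
    ay = anchors[None, :, 1]
    from .nn.autograd import stack
    x1 = ax - dist[:, :, 0] * sd[:, :, 0]
    y1 = ay - dist[:, :, 1] * sd[:, :, 0]
    x2 = ax + dist[:, :, 2] * sd[:, :, 0]
    y2 = ay + dist[:, :, 3] * sd[:, :, 0]
    return stack([x1, y1, x2, y2], axis=2)


def assign_targets(pred_boxes: np.ndarray, anchors: np.ndarray, strides: np.ndarray,
                   gt_boxes: np.ndarray, gt_cls: np.ndarray, topk: int = 10):
    """Center-prior + top-k IoU assignment for one image.

    Returns (anchor_idx, gt_idx) index arrays of the assigned pairs.
    """
    A, M = len(anchors), len(gt_boxes)
    if M == 0:
        return np.zeros(0, int), np.zeros(0, int)
    inside = (
        (anchors[:, 0:1] >= gt_boxes[None, :, 0])
        & (anchors[:, 0:1] <= gt_boxes[None, :, 2])
        & (anchors[:, 1:2] >= gt_boxes[None, :, 1])
        & (anchors[:, 1:2] <= gt_boxes[None, :, 3])
    )  # (A, M)
    from .evaluate import pairwise_iou

    iou = pairwise_iou(pred_boxes, gt_boxes)  # (A, M)
    score = np.where(inside, iou, -1.0)
    assign_gt = np.full(A, -1, int)
    assign_iou = np.full(A, -1.0)
    for m in range(M):
        cand = np.where(inside[:, m])[0]
        if len(cand) == 0:
            # box smaller than a grid cell: nearest stride-8 anchor center
            fine = np.where(strides == strides.min())[0]
            gcx = (gt_boxes[m, 0] + gt_boxes[m, 2]) / 2
            gcy = (gt_boxes[m, 1] + gt_boxes[m, 3]) / 2
            d = (anchors[fine, 0] - gcx) ** 2 + (anchors[fine, 1] - gcy) ** 2
            cand = fine[[np.argmin(d)]]
        order = cand[np.argsort(-iou[cand, m], kind="stable")][:topk]
        for a in order:
            if iou[a, m] > assign_iou[a]:
                assign_gt[a] = m
                assign_iou[a] = iou[a, m]
    fg = np.where(assign_gt >= 0)[0]
    return fg, assign_gt[fg]


def box_term(pred_boxes, gt_boxes, kind: str, image: B.ImageShape):
    """Mean box-regression loss over assigned pairs (works on tensors and
    arrays alike); this is the term toggled by ``box_loss_kind``."""
    if kind == "mpdiou":
        losses = B.batched_mpdiou_loss(pred_boxes, gt_boxes, image)
    elif kind == "ciou":
        losses = B.batched_ciou_loss(pred_boxes, gt_boxes)
    else:
        raise ValueError(f"unknown box loss {kind!r}")
    return losses.mean()


def compute_detection_loss(outputs, targets, cfg: ModelConfig,
                           input_size: int | None = None) -> tuple:
    """Composite loss for one batch.

    ``outputs`` is the head output (per-level (box, cls) tensor pairs);
    ``targets`` is a list (length batch) of (K, 5) arrays in normalized
    YOLO form ``[class, cx, cy, w, h]``.  Returns ``(total: Tensor,
    LossBreakdown)``.
    """
    size = input_size or cfg.input_size
    img = B.ImageShape(size, size)
    reg, cls = _flatten_head(outputs, cfg.reg_max, cfg.num_classes)
    n, A = cls.shape[0], cls.shape[1]
    anchors, strides = make_anchors(size)
    pred_boxes = decode_boxes(reg, anchors, strides)  # (N, A, 4)

    # assignment runs outside the graph
    with no_grad():
        pb = pred_boxes.data
    fg_b, fg_a, fg_gt_box, fg_gt_cls = [], [], [], []
    for b in range(n):
        t = np.asarray(targets[b], float).reshape(-1, 5)
        gt_xyxy = B.xywhn_to_xyxy(t[:, 1:], img) if len(t) else np.zeros((0, 4))
        ai, gi = assign_targets(pb[b], anchors, strides, gt_xyxy, t[:, 0])
        fg_b.append(np.full(len(ai), b))
        fg_a.append(ai)
        fg_gt_box.append(gt_xyxy[gi])
        fg_gt_cls.append(t[gi, 0].astype(int))
    fg_b = np.concatenate(fg_b).astype(int)
    fg_a = np.concatenate(fg_a).astype(int)
    fg_gt_box = np.concatenate(fg_gt_box).reshape(-1, 4)
    fg_gt_cls = np.concatenate(fg_gt_cls).astype(int)
    n_fg = len(fg_b)

    # classification: BCE over every anchor, positives get target 1
    t_cls = np.zeros((n, A, cfg.num_classes), np.float32)
    if n_fg:
        t_cls[fg_b, fg_a, fg_gt_cls] = 1.0
    p = cls.sigmoid().clip(1e-7, 1.0 - 1e-7)
    bce = -(t_cls * p.log() + (1.0 - t_cls) * (1.0 - p).log())
    cls_loss = bce.sum() * (1.0 / max(n_fg, 1))

    if n_fg:
        pred_fg = pred_boxes[fg_b, fg_a]  # (F, 4) tensor
        box_loss = box_term(pred_fg, fg_gt_box, cfg.box_loss_kind, img)

        # distribution-focal: two-bin soft cross-entropy on ltrb distances
        sd = strides[fg_a]
        tl = (anchors[fg_a, 0] - fg_gt_box[:, 0]) / sd
        tt = (anchors[fg_a, 1] - fg_gt_box[:, 1]) / sd
        tr = (fg_gt_box[:, 2] - anchors[fg_a, 0]) / sd
        tb = (fg_gt_box[:, 3] - anchors[fg_a, 1]) / sd
        tgt = np.clip(np.stack([tl, tt, tr, tb], 1), 0, cfg.reg_max - 1 - 1e-3)
        lo = np.floor(tgt).astype(int)
        w_hi = (tgt - lo).astype(np.float32)
        w_lo = 1.0 - w_hi
        logits_fg = reg[fg_b, fg_a]  # (F, 4, reg_max)
        logp = (logits_fg.softmax(axis=-1) + 1e-9).log()
        ii = np.arange(n_fg)[:, None] * np.ones((1, 4), int)
        jj = np.arange(4)[None, :] * np.ones((n_fg, 1), int)
        dfl = -(w_lo * logp[ii, jj, lo] + w_hi * logp[ii, jj, np.minimum(lo + 1, cfg.reg_max - 1)])
        dfl_loss = dfl.mean()
    else:
        box_loss = Tensor(0.0)
        dfl_loss = Tensor(0.0)

    total = cfg.box_weight * box_loss + cfg.cls_weight * cls_loss + cfg.dfl_weight * dfl_loss
    return total, LossBreakdown(
        box_loss=float(box_loss.data),
        cls_loss=float(cls_loss.data),
        dfl_loss=float(dfl_loss.data),
        total=float(total.data),
        num_assigned=n_fg,
    )
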