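"""Axis-aligned bounding boxes and IoU-family regression losses.

Boxes are handled in continuous corner form ``(x1, y1, x2, y2)`` with
``x2 >= x1`` and ``y2 >= y1``, the natural operand of corner-distance
penalties.  Conversions from the normalized center form used by YOLO label
files are explicit (:func:`xywhn_to_xyxy` / :func:`xyxy_to_xywhn`).

Three losses are provided:

* plain IoU (:func:`iou_breakdown`),
* CIoU — IoU plus a center-distance term ``rho^2/c^2`` and an
  aspect-ratio consistency term ``alpha * v``,
* MPDIoU — IoU minus the squared distances between corresponding
  top-left and bottom-right corners, each normalized by the squared
  image diagonal ``w^2 + h^2``.  ``L = 1 - MPDIoU``.

Scalar functions return dataclasses exposing every intermediate quantity;
the ``batched_*`` functions operate element-wise on ``(..., 4)`` arrays and
also accept autodiff tensors (see :mod:`leafdet.nn.autograd`), which is how
the detector's training loss delegates here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: guard added to the CIoU ``alpha`` denominator and to ``c^2``; identical
#: boxes would otherwise divide 0/0 when forming ``alpha``.
EPS = 1e-7


# ---------------------------------------------------------------------------
# generic helpers: duck-dispatch between numpy arrays and autodiff tensors
# ---------------------------------------------------------------------------

def _is_tensor(x) -> bool:
    return getattr(x, "_is_tensor", False)


def _maximum(a, b):
    if _is_tensor(a):
        return a.maximum(b)
    if _is_tensor(b):
        return b.maximum(a)
    return np.maximum(a, b)


def _minimum(a, b):
    if _is_tensor(a):
        return a.minimum(b)
    if _is_tensor(b):
        return b.minimum(a)
    return np.minimum(a, b)


def _atan_ratio(num, den):
    """arctan(num / den) for num, den >= 0, finite at den == 0 (-> pi/2)."""
    if _is_tensor(num) or _is_tensor(den):
        return (num / (den + EPS)).atan()
    return np.arctan2(num, den)


def _relu0(x):
    """max(x, 0) for either backend."""
    return _maximum(x, 0.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageShape:
    """Width/height of the image (or network input) the boxes live on."""

    w: int
    h: int

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"image dimensions must be positive, got {self.w}x{self.h}")

    @property
    def diag_sq(self) -> float:
        return float(self.w) ** 2 + float(self.h) ** 2


@dataclass(frozen=True)
class IoUBreakdown:
    intersection: float
    union: float
    iou: float
    degenerate: bool = False


@dataclass(frozen=True)
class CIoUResult:
    iou: float
    center_dist_sq: float
    enclosing_diag_sq: float
    v: float
    alpha: float
    loss: float


@dataclass(frozen=True)
class MPDIoUResult:
    iou: float
    d1_sq: float
    d2_sq: float
    mpdiou: float
    loss: float


def _validate_box(b, name: str) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if b.shape != (4,):
        raise ValueError(f"{name} must be (x1, y1, x2, y2), got shape {b.shape}")
    if b[2] < b[0] or b[3] < b[1]:
        raise ValueError(f"{name} violates corner form x2>=x1, y2>=y1: {b.tolist()}")
    return b


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def xywhn_to_xyxy(boxes, image: ImageShape):
    """Normalized YOLO center form ``(cx, cy, w, h)`` -> pixel corner form."""
    b = np.asarray(boxes, dtype=float)
    cx, cy, w, h = b[..., 0] * image.w, b[..., 1] * image.h, b[..., 2] * image.w, b[..., 3] * image.h
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=-1)


def xyxy_to_xywhn(boxes, image: ImageShape):
    """Pixel corner form -> normalized YOLO center form."""
    b = np.asarray(boxes, dtype=float)
    w = b[..., 2] - b[..., 0]
    h = b[..., 3] - b[..., 1]
    return np.stack(
        [
            (b[..., 0] + w / 2) / image.w,
            (b[..., 1] + h / 2) / image.h,
            w / image.w,
            h / image.h,
        ],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def iou_breakdown(pred, gt, *, strict: bool = False) -> IoUBreakdown:
    """Intersection, union and IoU of two corner-form boxes.

    The intersection is clamped to zero unless the candidate intersection
    rectangle has positive extent on both axes.  If both boxes are
    degenerate (zero area) the result is ``iou = 0`` with
    ``degenerate=True`` rather than a division error; with ``strict=True``
    that case raises instead.
    """
    p = _validate_box(pred, "pred")
    g = _validate_box(gt, "gt")
    a_p = (p[2] - p[0]) * (p[3] - p[1])
    a_g = (g[2] - g[0]) * (g[3] - g[1])
    x1i, y1i = max(p[0], g[0]), max(p[1], g[1])
    x2i, y2i = min(p[2], g[2]), min(p[3], g[3])
    inter = (x2i - x1i) * (y2i - y1i) if (x2i > x1i and y2i > y1i) else 0.0
    union = a_p + a_g - inter
    if union <= 0.0:
        if strict:
            raise ValueError("both boxes are degenerate (zero area)")
        return IoUBreakdown(0.0, 0.0, 0.0, degenerate=True)
    return IoUBreakdown(float(inter), float(union), float(inter / union))


def ciou_loss(pred, gt) -> CIoUResult:
    """CIoU loss ``1 - IoU + rho^2/c^2 + alpha*v`` for one box pair.

    ``v`` measures aspect-ratio inconsistency via arctans of width/height
    ratios; the ratio is evaluated as ``arctan2(w, h)`` so zero-height
    boxes hit the ``pi/2`` limit instead of overflowing.  ``alpha`` is the
    trade-off ``v / (1 - IoU + v)``, guarded by :data:`EPS`.
    """
    p = _validate_box(pred, "pred")
    g = _validate_box(gt, "gt")
    if (g[2] - g[0]) * (g[3] - g[1]) <= 0:
        raise ValueError("ground-truth box must have positive area")
    iou = iou_breakdown(pred, gt).iou

    pcx, pcy = (p[0] + p[2]) / 2, (p[1] + p[3]) / 2
    gcx, gcy = (g[0] + g[2]) / 2, (g[1] + g[3]) / 2
    rho_sq = (pcx - gcx) ** 2 + (pcy - gcy) ** 2

    cw = max(p[2], g[2]) - min(p[0], g[0])
    ch = max(p[3], g[3]) - min(p[1], g[1])
    c_sq = cw**2 + ch**2 + EPS

    w, h = p[2] - p[0], p[3] - p[1]
    wg, hg = g[2] - g[0], g[3] - g[1]
    v = (4 / np.pi**2) * (np.arctan2(wg, hg) - np.arctan2(w, h)) ** 2
    alpha = v / ((1 - iou) + v + EPS)
    loss = 1 - iou + rho_sq / c_sq + alpha * v
    return CIoUResult(float(iou), float(rho_sq), float(c_sq), float(v), float(alpha), float(loss))


def mpdiou_loss(pred, gt, image: ImageShape) -> MPDIoUResult:
    """MPDIoU loss for one box pair on an image of shape ``image``.

    ``d1^2`` / ``d2^2`` are the squared Euclidean distances between the two
    top-left and the two bottom-right corners; both are normalized by the
    squared image diagonal ``h^2 + w^2``.  ``MPDIoU = IoU - d1^2/(h^2+w^2)
    - d2^2/(h^2+w^2)`` and the loss is ``1 - MPDIoU``.
    """
    p = _validate_box(pred, "pred")
    g = _validate_box(gt, "gt")
    iou = iou_breakdown(pred, gt).iou
    d1_sq = (p[0] - g[0]) ** 2 + (p[1] - g[1]) ** 2
    d2_sq = (p[2] - g[2]) ** 2 + (p[3] - g[3]) ** 2
    mpd = iou - d1_sq / image.diag_sq - d2_sq / image.diag_sq
    return MPDIoUResult(float(iou), float(d1_sq), float(d2_sq), float(mpd), float(1 - mpd))


# ---------------------------------------------------------------------------
# batched API (numpy arrays or autodiff tensors, element-wise on (..., 4))
# ---------------------------------------------------------------------------

def batched_iou(pred, gt):
    """Element-wise IoU of two stacks of corner-form boxes.

    Degenerate pairs (zero union) quietly yield 0 — inside a training loop
    an exception would abort the step for one bad box.
    """
    inter_w = _relu0(_minimum(pred[..., 2], gt[..., 2]) - _maximum(pred[..., 0], gt[..., 0]))
    inter_h = _relu0(_minimum(pred[..., 3], gt[..., 3]) - _maximum(pred[..., 1], gt[..., 1]))
    inter = inter_w * inter_h
    a_p = (pred[..., 2] - pred[..., 0]) * (pred[..., 3] - pred[..., 1])
    a_g = (gt[..., 2] - gt[..., 0]) * (gt[..., 3] - gt[..., 1])
    union = a_p + a_g - inter
    return inter / (union + EPS)


def batched_ciou_loss(pred, gt):
    """Element-wise CIoU loss; same formula as :func:`ciou_loss`."""
    iou = batched_iou(pred, gt)
    rho_sq = (
        ((pred[..., 0] + pred[..., 2]) - (gt[..., 0] + gt[..., 2])) ** 2
        + ((pred[..., 1] + pred[..., 3]) - (gt[..., 1] + gt[..., 3])) ** 2
    ) * 0.25
    cw = _maximum(pred[..., 2], gt[..., 2]) - _minimum(pred[..., 0], gt[..., 0])
    ch = _maximum(pred[..., 3], gt[..., 3]) - _minimum(pred[..., 1], gt[..., 1])
    c_sq = cw * cw + ch * ch + EPS
    v = (4 / np.pi**2) * (
        _atan_ratio(gt[..., 2] - gt[..., 0], gt[..., 3] - gt[..., 1])
        - _atan_ratio(pred[..., 2] - pred[..., 0], pred[..., 3] - pred[..., 1])
    ) ** 2
    alpha = v / ((1.0 - iou) + v + EPS)
    return 1.0 - iou + rho_sq / c_sq + alpha * v


def batched_mpdiou(pred, gt, image: ImageShape):
    """Element-wise MPDIoU (the similarity, not the loss)."""
    iou = batched_iou(pred, gt)
    d1_sq = (pred[..., 0] - gt[..., 0]) ** 2 + (pred[..., 1] - gt[..., 1]) ** 2
    d2_sq = (pred[..., 2] - gt[..., 2]) ** 2 + (pred[..., 3] - gt[..., 3]) ** 2
    return iou - d1_sq / image.diag_sq - d2_sq / image.diag_sq


def batched_mpdiou_loss(pred, gt, image: ImageShape):
    """Element-wise MPDIoU loss ``1 - MPDIoU``."""
    return 1.0 - batched_mpdiou(pred, gt, image)
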