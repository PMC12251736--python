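"""Inference: decode head outputs, class-wise NMS, checkpoint save/load."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .detect_loss import decode_boxes, make_anchors, _flatten_head
from .model import DetectionModel
from .nn.autograd import Tensor, no_grad

__all__ = ["Detection", "nms", "detect", "predict_array", "save_checkpoint",
           "load_checkpoint"]


@dataclass(frozen=True)
class Detection:
    """One detection in network-input pixel coordinates."""

    box: tuple  # (x1, y1, x2, y2), clipped to the input frame
    class_id: int
    confidence: float


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices (desc. score)."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while len(order):
        i = order[0]
        keep.append(i)
        if len(order) == 1:
            break
        rest = order[1:]
        tl = np.maximum(boxes[i, :2], boxes[rest, :2])
        br = np.minimum(boxes[i, 2:], boxes[rest, 2:])
        wh = np.clip(br - tl, 0, None)
        inter = wh[:, 0] * wh[:, 1]
        area_i = (boxes[i, 2] - boxes[i, 0]) * (boxes[i, 3] - boxes[i, 1])
        area_r = (boxes[rest, 2] - boxes[rest, 0]) * (boxes[rest, 3] - boxes[rest, 1])
        iou = inter / np.maximum(area_i + area_r - inter, 1e-12)
        order = rest[iou <= iou_thr]
    return np.asarray(keep, int)


def predict_array(model: DetectionModel, image: np.ndarray,
                  conf_thr: float = 0.25, iou_thr: float = 0.45) -> list:
    """Run one already-resized HxWx3 uint8 image through the detector."""
    cfg = model.cfg
    size = cfg.input_size
    if image.shape[:2] != (size, size):
        image = np.asarray(Image.fromarray(image).resize((size, size), Image.BILINEAR))
    x = (image.astype(np.float32) / 255.0).transpose(2, 0, 1)[None]
    was_training = model.training
    model.eval()
    with no_grad():
        outputs = model(Tensor(x))
        reg, cls = _flatten_head(outputs, cfg.reg_max, cfg.num_classes)
        anchors, strides = make_anchors(size)
        boxes = decode_boxes(reg, anchors, strides).data[0]  # (A, 4)
        from .nn.autograd import _stable_sigmoid

        scores = _stable_sigmoid(cls.data[0])  # (A, nc)
    model.train(was_training)

    cls_id = scores.argmax(axis=1)
    conf = scores.max(axis=1)
    m = conf >= conf_thr
    boxes, cls_id, conf = boxes[m], cls_id[m], conf[m]
    boxes[:, [0, 2]] = np.clip(boxes[:, [0, 2]], 0, size)
    boxes[:, [1, 3]] = np.clip(boxes[:, [1, 3]], 0, size)

    detections = []
    for c in np.unique(cls_id):
        sel = np.where(cls_id == c)[0]
        for k in nms(boxes[sel], conf[sel], iou_thr):
            i = sel[k]
            detections.append(Detection(tuple(float(v) for v in boxes[i]),
                                        int(c), float(conf[i])))
    detections.sort(key=lambda d: -d.confidence)
    return detections


def detect(model: DetectionModel, image_path, conf_thr: float = 0.25,
           iou_thr: float = 0.45) -> list:
    """Detect lesions in an image file (resized to the model input size)."""
    img = np.asarray(Image.open(image_path).convert("RGB"))
    return predict_array(model, img, conf_thr, iou_thr)


def save_checkpoint(model: DetectionModel, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **model.state_dict())


def load_checkpoint(model: DetectionModel, path):
    with np.load(Path(path)) as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model
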