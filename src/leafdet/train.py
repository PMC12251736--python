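"""CPU-scale toy training loop.

Optimization follows the reference field configuration — SGD with momentum
0.937 and weight decay 5e-4, initial learning rate 1e-2 — scaled down to a
desk-size problem: width multiple 0.25, 160 px inputs, a few hundred
synthetic images, a short schedule with two warmup epochs and linear decay.
The loop is fully seeded: identical seeds give identical loss trajectories.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as dio
from .detect_loss import compute_detection_loss
from .evaluate import evaluate_detections
from .infer import predict_array
from .model import DetectionModel, ModelConfig, build_model
from .nn.autograd import Tensor
from .nn.modules import SGD

__all__ = ["TrainReport", "toy_train", "evaluate_model"]


@dataclass
class TrainReport:
    epoch_losses: list = field(default_factory=list)  # dicts: box/cls/dfl/total
    val_map50: list = field(default_factory=list)
    final_map50: float = 0.0
    epochs: int = 0
    seconds: float = 0.0

    @property
    def smoothed(self):
        """3-epoch moving average of the total loss."""
        t = np.array([e["total"] for e in self.epoch_losses])
        if len(t) < 3:
            return t
        return np.convolve(t, np.ones(3) / 3, mode="valid")


def _load_split(manifest: dict, split: str):
    images, labels = [], []
    for img_path, ann in dio.iter_split(manifest, split):
        images.append(dio.read_image(img_path))
        labels.append(ann)
    return images, labels


def evaluate_model(model: DetectionModel, images, labels,
                   conf_thr: float = 0.05, iou_thr: float = 0.5) -> float:
    """mAP@0.5 of the model on an in-memory image/label list (%)."""
    size = model.cfg.input_size
    preds, gts = {}, {}
    for i, (img, ann) in enumerate(zip(images, labels)):
        dets = predict_array(model, img, conf_thr=conf_thr)
        preds[i] = np.array(
            [[*d.box, d.confidence, d.class_id] for d in dets], float
        ).reshape(-1, 6)
        ann = np.asarray(ann, float).reshape(-1, 5)
        cx, cy, w, h = ann[:, 1] * size, ann[:, 2] * size, ann[:, 3] * size, ann[:, 4] * size
        gts[i] = np.stack(
            [cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2, ann[:, 0]], axis=1
        ) if len(ann) else np.zeros((0, 5))
    return evaluate_detections(preds, gts, iou_thr=iou_thr).map50


def toy_train(dataset_dir, cfg: ModelConfig, epochs: int = 14, seed: int = 0,
              batch_size: int = 16, lr0: float = 1e-2,
              eval_every: int = 0, verbose: bool = False) -> tuple:
    """Train a detector on a YOLO-layout dataset; returns (model, report).

    ``eval_every=k`` computes validation mAP every k epochs (0 = only at
    the end).  Raises on an empty dataset.
    """
    manifest = dio.read_manifest(Path(dataset_dir) / "data.yaml")
    train_imgs, train_labels = _load_split(manifest, "train")
    val_imgs, val_labels = _load_split(manifest, "val")
    if not train_imgs:
        raise ValueError(f"no training images under {dataset_dir}")

    size = cfg.input_size
    model = build_model(cfg, seed=seed)
    opt = SGD(model.parameters(), lr=lr0, momentum=0.937, weight_decay=5e-4)
    rng = np.random.default_rng(seed)
    report = TrainReport(epochs=epochs)
    t0 = time.time()

    xs = np.stack([im.astype(np.float32).transpose(2, 0, 1) / 255.0 for im in train_imgs])
    n = len(xs)
    steps = max(1, n // batch_size)

    for epoch in range(epochs):
        # two warmup epochs, then linear decay to 10% of lr0
        if epoch < 2:
            lr = lr0 * (0.1 + 0.45 * epoch)
        else:
            frac = (epoch - 2) / max(1, epochs - 3)
            lr = lr0 * (1.0 - 0.9 * frac)
        opt.lr = lr

        order = rng.permutation(n)
        sums = {"box": 0.0, "cls": 0.0, "dfl": 0.0, "total": 0.0}
        for s in range(steps):
            idx = order[s * batch_size : (s + 1) * batch_size]
            batch = Tensor(xs[idx])
            targets = [train_labels[i] for i in idx]
            outputs = model(batch)
            total, parts = compute_detection_loss(outputs, targets, cfg, input_size=size)
            opt.zero_grad()
            total.backward()
            opt.step()
            sums["box"] += parts.box_loss
            sums["cls"] += parts.cls_loss
            sums["dfl"] += parts.dfl_loss
            sums["total"] += parts.total
        losses = {k: v / steps for k, v in sums.items()}
        report.epoch_losses.append(losses)
        if eval_every and (epoch + 1) % eval_every == 0:
            report.val_map50.append(evaluate_model(model, val_imgs, val_labels))
        if verbose:
            m = f" val mAP50={report.val_map50[-1]:.1f}" if (
                eval_every and (epoch + 1) % eval_every == 0) else ""
            print(f"epoch {epoch + 1:3d}/{epochs} lr={lr:.4f} "
                  f"loss={losses['total']:.3f} (box {losses['box']:.3f} "
                  f"cls {losses['cls']:.3f} dfl {losses['dfl']:.3f}){m}")

    report.final_map50 = evaluate_model(model, val_imgs, val_labels)
    report.val_map50.append(report.final_map50)
    report.seconds = time.time() - t0
    return model, report
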