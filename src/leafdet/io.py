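"""Dataset IO: YOLO-format labels, PNG images, YAML manifests.

Label files carry one object per line, ``class cx cy w h`` with
center/size normalized to [0, 1].  A dataset directory looks like::

    out/
      data.yaml            # path, train/val/test image dirs, names
      images/{train,val,test}/*.png
      labels/{train,val,test}/*.txt
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "read_labels",
    "write_labels",
    "read_image",
    "write_image",
    "write_manifest",
    "read_manifest",
    "iter_split",
    "label_path_for",
]


def read_labels(path) -> np.ndarray:
    """Read one YOLO label file -> (K, 5) array [class, cx, cy, w, h]."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        return np.zeros((0, 5))
    rows = []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 5:
            raise ValueError(f"{path}: malformed label line {line!r}")
        rows.append([float(parts[0])] + [float(v) for v in parts[1:]])
    arr = np.asarray(rows, float)
    if len(arr) and (arr[:, 1:] < -1e-6).any() or (arr[:, 1:] > 1 + 1e-6).any():
        raise ValueError(f"{path}: normalized coordinates outside [0, 1]")
    return arr


def write_labels(path, annotations: np.ndarray):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ann = np.asarray(annotations, float).reshape(-1, 5)
    lines = [
        f"{int(a[0])} {a[1]:.6f} {a[2]:.6f} {a[3]:.6f} {a[4]:.6f}" for a in ann
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_image(path, image: np.ndarray):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(image, np.uint8)).save(path)


def write_manifest(out_dir, class_names: list, splits=("train", "val", "test")) -> Path:
    out_dir = Path(out_dir)
    manifest = {
        "path": str(out_dir.resolve()),
        **{s: f"images/{s}" for s in splits},
        "nc": len(class_names),
        "names": {i: n for i, n in enumerate(class_names)},
    }
    p = out_dir / "data.yaml"
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return p


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def label_path_for(image_path) -> Path:
    """images/<split>/x.png -> labels/<split>/x.txt"""
    p = Path(image_path)
    parts = list(p.parts)
    idx = len(parts) - 1 - parts[::-1].index("images")
    parts[idx] = "labels"
    return Path(*parts).with_suffix(".txt")


def iter_split(manifest: dict, split: str):
    """Yield (image_path, annotations) pairs for one split."""
    root = Path(manifest["path"])
    img_dir = root / manifest[split]
    for img_path in sorted(img_dir.glob("*.png")):
        yield img_path, read_labels(label_path_for(img_path))
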