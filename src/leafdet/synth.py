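"""Synthetic leaf-disease scene generator, augmentation suite and dataset
builders.

The generator emulates the statistical structure of field imagery of
diseased tea leaves — not botany: leaves are textured elliptical masks,
lesions are class-distinct colored blobs, complex backgrounds are
multi-color clutter.  What it does reproduce faithfully, and what the rest
of the package exercises, are the factors that make field detection hard:

* simple vs. complex backgrounds (tied to :mod:`leafdet.complexity`),
* multi-leaf occlusion with painter's-order visibility (a lesion hidden by
  a later leaf loses those pixels, possibly its whole annotation),
* multiplicative illumination gradients,
* lesion area fractions from several percent of the image down to the
  sub-0.5% "small lesion" regime, across >= 3 disease classes.

Everything is deterministic given ``(spec, seed)``.  Annotations are exact
bounding boxes of the *visible* lesion mask, in normalized YOLO form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image, ImageEnhance
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv

from . import io as dio

log = logging.getLogger("leafdet.synth")

__all__ = [
    "SceneSpec",
    "generate_scene",
    "generate_dataset",
    "augment",
    "PRESET_SPECS",
    "CLASS_NAMES",
]

#: stylized disease classes (appearance models cycle through these)
CLASS_NAMES = ["brown_blight", "grey_blight", "algal_spot", "white_spot", "leaf_rust"]

# base HSV appearance per class: (hue, sat, val) of the blob fill
_LESION_HSV = {
    0: (0.07, 0.80, 0.45),  # brown
    1: (0.10, 0.10, 0.70),  # pale grey
    2: (0.05, 0.90, 0.75),  # orange/rust
    3: (0.12, 0.05, 0.95),  # whitish
    4: (0.09, 0.95, 0.60),  # rust-red
}


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of one synthetic scene."""

    image_size: int = 160
    n_leaves: int = 1
    background_kind: str = "simple"  # "simple" | "complex"
    lesion_classes: tuple = (0, 1, 2)
    lesions_per_leaf: tuple = (1, 1)  # inclusive range
    lesion_area_fraction: tuple = (0.01, 0.05)  # of image area
    occlusion_level: float = 0.0  # target pairwise leaf-mask overlap
    illumination_gradient: float = 0.0  # brightness ramp amplitude in [0, 1]

    def __post_init__(self):
        if self.background_kind not in ("simple", "complex"):
            raise ValueError(f"unknown background kind {self.background_kind!r}")
        if self.lesion_area_fraction[0] <= 0:
            raise ValueError("lesion_area_fraction must be positive")
        if not 0 <= self.occlusion_level <= 1:
            raise ValueError("occlusion_level must lie in [0, 1]")
        if len(self.lesion_classes) < 1:
            raise ValueError("need at least one lesion class")
        if self.n_leaves < 1:
            raise ValueError("need at least one leaf")
        if self.n_leaves > max(1, (self.image_size // 40) ** 2 * 2):
            raise ValueError(
                f"infeasible spec: {self.n_leaves} leaves cannot fit a "
                f"{self.image_size}px scene"
            )


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------

def _smooth_noise(rng, size, sigma, lo=0.0, hi=1.0):
    z = rng.standard_normal((size, size))
    z = ndimage.gaussian_filter(z, sigma)
    z = (z - z.min()) / max(np.ptp(z), 1e-9)
    return lo + (hi - lo) * z


def _ellipse_mask(size, cy, cx, ry, rx, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    y, x = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = (c * x + s * y) / max(rx, 1e-6)
    v = (-s * x + c * y) / max(ry, 1e-6)
    return u * u + v * v <= 1.0


def _simple_background(rng, size):
    hue = rng.uniform(0.2, 0.36)  # grassy green family
    base = np.array(hsv2rgb(np.array([[[hue, rng.uniform(0.25, 0.45),
                                        rng.uniform(0.55, 0.8)]]]))[0, 0])
    img = np.empty((size, size, 3))
    ramp = np.linspace(-0.005, 0.005, size)[None, :, None]
    img[:] = base[None, None, :]
    img = img * (1.0 + ramp)
    img += rng.normal(0, 0.002, img.shape)
    return np.clip(img * 255, 0, 255)


def _complex_background(rng, size):
    # layered clutter: smoothed color fields plus many hard-edged shapes
    h = _smooth_noise(rng, size, sigma=6, lo=0.0, hi=1.0)
    s = _smooth_noise(rng, size, sigma=8, lo=0.3, hi=0.9)
    v = _smooth_noise(rng, size, sigma=5, lo=0.25, hi=0.95)
    img = hsv2rgb(np.stack([h, s, v], axis=-1)) * 255
    n_shapes = max(20, (size * size) // 600)
    for _ in range(n_shapes):
        cy, cx = rng.uniform(0, size, 2)
        ry, rx = rng.uniform(size * 0.02, size * 0.12, 2)
        m = _ellipse_mask(size, cy, cx, ry, rx, rng.uniform(0, np.pi))
        color = hsv2rgb(np.array([[[rng.uniform(0, 1), rng.uniform(0.4, 1.0),
                                    rng.uniform(0.2, 1.0)]]]))[0, 0] * 255
        img[m] = 0.75 * color + 0.25 * img[m]
    img += rng.normal(0, 6.0, img.shape)
    return np.clip(img, 0, 255)


def _leaf_texture(rng, size, mask, cy, cx, theta):
    hue = rng.uniform(0.23, 0.34)
    sat = rng.uniform(0.5, 0.8)
    val = rng.uniform(0.35, 0.6)
    tex = _smooth_noise(rng, size, sigma=2.5, lo=-0.10, hi=0.10)
    hsv = np.zeros((size, size, 3))
    hsv[..., 0] = hue
    hsv[..., 1] = sat
    hsv[..., 2] = np.clip(val + tex, 0.05, 1.0)
    rgb = hsv2rgb(hsv) * 255
    # venation: a central vein along the major axis plus oblique side veins
    yy, xx = np.mgrid[0:size, 0:size]
    c, s = np.cos(theta), np.sin(theta)
    u = c * (xx - cx) + s * (yy - cy)   # along the axis
    v = -s * (xx - cx) + c * (yy - cy)  # across the axis
    veins = np.abs(v) < 0.8
    pitch = max(4, size // 20)
    veins |= (np.abs((v - 0.9 * np.abs(u)) % pitch) < 0.7)
    rgb[mask & veins] *= 0.72
    return rgb, mask


def _render_lesion(rng, size, cls, cy, cx, radius):
    """Class-distinct blob mask + color field for one lesion."""
    ry = radius * rng.uniform(0.8, 1.2)
    rx = radius * rng.uniform(0.8, 1.2)
    blob = _ellipse_mask(size, cy, cx, ry, rx, rng.uniform(0, np.pi))
    if cls % 2 == 1:  # ragged outline for odd classes
        rough = _smooth_noise(rng, size, sigma=1.5) > 0.35
        blob &= rough | ndimage.binary_erosion(blob, iterations=max(1, int(radius * 0.3)))
    hue, sat, val = _LESION_HSV[cls % len(_LESION_HSV)]
    jitter = rng.uniform(-0.015, 0.015)
    tex = _smooth_noise(rng, size, sigma=1.0, lo=-0.12, hi=0.12)
    hsv = np.zeros((size, size, 3))
    hsv[..., 0] = np.clip(hue + jitter, 0, 1)
    hsv[..., 1] = sat
    hsv[..., 2] = np.clip(val + tex, 0.05, 1.0)
    color = hsv2rgb(hsv) * 255
    # darker rim to give the lesion an edge
    rim = blob & ~ndimage.binary_erosion(blob, iterations=2)
    color[rim] *= 0.55
    return blob, color


def generate_scene(spec: SceneSpec, seed: int):
    """Render one scene.

    Returns ``(image uint8 HxWx3, annotations (K, 5) [cls, cx, cy, w, h]
    normalized, metadata dict)``.  Metadata records the achieved maximum
    pairwise leaf overlap, per-lesion visible area fractions, and the
    illumination ramp applied (axis "x", signed amplitude).
    """
    rng = np.random.default_rng(seed)
    size = spec.image_size

    if spec.background_kind == "simple":
        canvas = _simple_background(rng, size)
    else:
        canvas = _complex_background(rng, size)

    # --- leaf placement ---------------------------------------------------
    owner = np.full((size, size), -1, int)  # painter's-order visibility map
    leaf_masks = []
    r_base = size * (0.30 if spec.n_leaves <= 2 else 0.24)
    anchor = np.array([size / 2, size / 2]) + rng.uniform(-size * 0.08, size * 0.08, 2)
    for li in range(spec.n_leaves):
        ry = r_base * rng.uniform(0.75, 1.0)
        rx = r_base * rng.uniform(0.45, 0.7)
        if li == 0 or spec.occlusion_level <= 0:
            cy, cx = (anchor if li == 0
                      else rng.uniform(size * 0.2, size * 0.8, 2))
        else:
            # offset from the anchor leaf scaled to hit the overlap target
            d = (1.0 - 0.85 * spec.occlusion_level) * (r_base * 1.1)
            ang = rng.uniform(0, 2 * np.pi)
            cy = np.clip(anchor[0] + d * np.sin(ang), size * 0.15, size * 0.85)
            cx = np.clip(anchor[1] + d * np.cos(ang), size * 0.15, size * 0.85)
        theta = rng.uniform(0, np.pi)
        mask = _ellipse_mask(size, cy, cx, ry, rx, theta)
        leaf_masks.append(mask)
        rgb, _ = _leaf_texture(rng, size, mask, cy, cx, theta)
        canvas[mask] = rgb[mask]
        owner[mask] = li

    overlaps = []
    for i in range(len(leaf_masks)):
        for j in range(i + 1, len(leaf_masks)):
            inter = (leaf_masks[i] & leaf_masks[j]).sum()
            denom = min(leaf_masks[i].sum(), leaf_masks[j].sum())
            overlaps.append(inter / max(denom, 1))
    max_overlap = float(max(overlaps)) if overlaps else 0.0

    # --- lesions ----------------------------------------------------------
    annotations = []
    lesion_fractions = []
    lo, hi = spec.lesions_per_leaf
    for li, mask in enumerate(leaf_masks):
        n_lesions = int(rng.integers(lo, hi + 1))
        ys, xs = np.where(mask)
        if len(ys) == 0:
            continue
        for _ in range(n_lesions):
            cls = int(rng.choice(spec.lesion_classes))
            frac = rng.uniform(*spec.lesion_area_fraction)
            radius = max(1.5, np.sqrt(frac * size * size / np.pi))
            # prefer centers well inside the leaf
            interior = ndimage.binary_erosion(mask, iterations=max(1, int(radius)))
            iy, ix = np.where(interior)
            if len(iy) == 0:
                iy, ix = ys, xs
            k = int(rng.integers(len(iy)))
            blob, color = _render_lesion(rng, size, cls, iy[k], ix[k], radius)
            blob &= mask
            if blob.sum() < 4:
                continue
            canvas[blob] = color[blob]
            visible = blob & (owner == li)
            if visible.sum() < 4:  # fully hidden by a later leaf
                continue
            by, bx = np.where(visible)
            x1, x2 = bx.min(), bx.max() + 1
            y1, y2 = by.min(), by.max() + 1
            annotations.append([
                cls,
                (x1 + x2) / 2 / size,
                (y1 + y2) / 2 / size,
                (x2 - x1) / size,
                (y2 - y1) / size,
            ])
            lesion_fractions.append(visible.sum() / (size * size))

    # --- illumination ------------------------------------------------------
    sign = 1.0
    if spec.illumination_gradient > 0:
        a = spec.illumination_gradient
        sign = float(rng.choice([-1.0, 1.0]))
        ramp = 1.0 - a / 2 + a * np.linspace(0, 1, size)
        if sign < 0:
            ramp = ramp[::-1]
        canvas = canvas * ramp[None, :, None]

    image = np.clip(canvas, 0, 255).astype(np.uint8)
    metadata = {
        "seed": int(seed),
        "background_kind": spec.background_kind,
        "max_leaf_overlap": max_overlap,
        "lesion_area_fractions": lesion_fractions,
        "illumination_axis": "x",
        "illumination_amplitude": float(sign * spec.illumination_gradient),
    }
    return image, np.asarray(annotations, float).reshape(-1, 5), metadata


# ---------------------------------------------------------------------------
# augmentation suite
# ---------------------------------------------------------------------------

_AUG_OPS = ("rotation", "translation", "mirror", "sharpness", "noise",
            "cutout", "color_dither")


def _boxes_to_corners(ann, size):
    cx, cy, w, h = (ann[:, 1] * size, ann[:, 2] * size, ann[:, 3] * size, ann[:, 4] * size)
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def _corners_to_boxes(cls, corners, size):
    x1, y1, x2, y2 = corners.T
    return np.stack([cls, (x1 + x2) / 2 / size, (y1 + y2) / 2 / size,
                     (x2 - x1) / size, (y2 - y1) / size], axis=1)


def augment(image, annotations, ops_spec, seed: int):
    """Apply a sequence of augmentations.

    ``ops_spec`` is a list whose entries are op names or ``(name, params)``
    pairs; supported names: rotation, translation, mirror, sharpness,
    noise, cutout, color_dither.  Geometric ops transform boxes with the
    pixels (rotation keeps the axis-aligned bbox of the rotated corners);
    photometric ops and cutout leave boxes untouched.  Boxes pushed fully
    outside the image are dropped and the drop is logged.  Deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    img = np.asarray(image, np.uint8).copy()
    ann = np.asarray(annotations, float).reshape(-1, 5).copy()
    size = img.shape[0]

    for entry in ops_spec:
        name, params = entry if isinstance(entry, tuple) else (entry, {})
        if name not in _AUG_OPS:
            raise ValueError(f"unknown augmentation {name!r}")

        if name == "mirror":
            img = img[:, ::-1].copy()
            if len(ann):
                ann[:, 1] = 1.0 - ann[:, 1]

        elif name == "translation":
            dx = params.get("dx", rng.uniform(-0.1, 0.1))
            dy = params.get("dy", rng.uniform(-0.1, 0.1))
            px, py = int(round(dx * size)), int(round(dy * size))
            out = np.full_like(img, 114)
            src_y = slice(max(0, -py), min(size, size - py))
            src_x = slice(max(0, -px), min(size, size - px))
            dst_y = slice(max(0, py), min(size, size + py))
            dst_x = slice(max(0, px), min(size, size + px))
            out[dst_y, dst_x] = img[src_y, src_x]
            img = out
            if len(ann):
                ann[:, 1] += px / size
                ann[:, 2] += py / size

        elif name == "rotation":
            deg = params.get("degrees", rng.uniform(-15, 15))
            pil = Image.fromarray(img).rotate(-deg, resample=Image.BILINEAR,
                                              fillcolor=(114, 114, 114))
            img = np.asarray(pil)
            if len(ann):
                th = np.deg2rad(deg)
                c0 = size / 2
                corners = _boxes_to_corners(ann, size)
                pts = np.stack([
                    corners[:, [0, 1]], corners[:, [2, 1]],
                    corners[:, [0, 3]], corners[:, [2, 3]],
                ], axis=1) - c0  # (K, 4, 2) xy
                rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
                pts = pts @ rot.T + c0
                new = np.stack([
                    pts[..., 0].min(1), pts[..., 1].min(1),
                    pts[..., 0].max(1), pts[..., 1].max(1),
                ], axis=1)
                ann = _corners_to_boxes(ann[:, 0], new, size)

        elif name == "sharpness":
            factor = params.get("factor", rng.uniform(0.5, 2.0))
            img = np.asarray(ImageEnhance.Sharpness(Image.fromarray(img)).enhance(factor))

        elif name == "noise":
            sigma = params.get("sigma", rng.uniform(2, 8))
            img = np.clip(img + rng.normal(0, sigma, img.shape), 0, 255).astype(np.uint8)

        elif name == "cutout":
            n = params.get("patches", int(rng.integers(1, 4)))
            for _ in range(n):
                frac = rng.uniform(0.02, 0.10)
                side = int(np.sqrt(frac) * size)
                y0 = int(rng.integers(0, max(1, size - side)))
                x0 = int(rng.integers(0, max(1, size - side)))
                img[y0 : y0 + side, x0 : x0 + side] = 114

        elif name == "color_dither":
            amount = params.get("amount", 0.2)
            hsv = rgb2hsv(img / 255.0)
            hsv[..., 0] = (hsv[..., 0] + rng.uniform(-amount, amount) * 0.5) % 1.0
            hsv[..., 1] = np.clip(hsv[..., 1] * (1 + rng.uniform(-amount, amount)), 0, 1)
            hsv[..., 2] = np.clip(hsv[..., 2] * (1 + rng.uniform(-amount, amount)), 0, 1)
            img = (hsv2rgb(hsv) * 255).astype(np.uint8)

        # clip geometric results and drop boxes that left the frame
        if name in ("mirror", "translation", "rotation") and len(ann):
            corners = _boxes_to_corners(ann, size)
            corners[:, [0, 2]] = np.clip(corners[:, [0, 2]], 0, size)
            corners[:, [1, 3]] = np.clip(corners[:, [1, 3]], 0, size)
            keep = (corners[:, 2] - corners[:, 0] >= 1) & (corners[:, 3] - corners[:, 1] >= 1)
            if not keep.all():
                log.info("augment(%s): dropped %d box(es) leaving the frame",
                         name, int((~keep).sum()))
            ann = _corners_to_boxes(ann[keep, 0], corners[keep], size)

    return img, ann


# ---------------------------------------------------------------------------
# dataset builders
# ---------------------------------------------------------------------------

#: named study conditions for the challenge subsets
PRESET_SPECS = {
    "easy": SceneSpec(n_leaves=1, background_kind="simple",
                      lesion_area_fraction=(0.02, 0.06)),
    "occlusion": SceneSpec(n_leaves=3, background_kind="complex",
                           occlusion_level=0.5,
                           lesion_area_fraction=(0.01, 0.05)),
    "lowlight": SceneSpec(n_leaves=2, background_kind="complex",
                          illumination_gradient=0.7,
                          lesion_area_fraction=(0.01, 0.05)),
    "smalllesion": SceneSpec(n_leaves=1, background_kind="complex",
                             lesion_area_fraction=(0.001, 0.005)),
    "complex": SceneSpec(n_leaves=2, background_kind="complex",
                         lesion_area_fraction=(0.01, 0.05)),
}


def split_sizes(n: int, ratios=(0.7, 0.2, 0.1)):
    """7:2:1 split; val/test round to nearest, train takes the remainder."""
    n_val = int(round(ratios[1] * n))
    n_test = int(round(ratios[2] * n))
    return n - n_val - n_test, n_val, n_test


def generate_dataset(spec, n_images: int, out_dir, seed: int = 0,
                     ratios=(0.7, 0.2, 0.1), preset: str | None = None,
                     class_names=None):
    """Write a YOLO-layout dataset of ``n_images`` scenes.

    ``spec`` may be a :class:`SceneSpec` or a preset name from
    :data:`PRESET_SPECS`.  The "lowlight" preset additionally applies a
    post-hoc brightness/contrast perturbation on top of the rendered
    illumination ramp.  Returns the manifest path.
    """
    if isinstance(spec, str):
        preset = spec
        spec = PRESET_SPECS[spec]
    if n_images < 10:
        raise ValueError("need at least 10 images for a 7:2:1 split")
    out_dir = Path(out_dir)
    n_train, n_val, n_test = split_sizes(n_images, ratios)
    split_of = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    names = list(class_names) if class_names else [
        CLASS_NAMES[c % len(CLASS_NAMES)] for c in spec.lesion_classes
    ]
    rng = np.random.default_rng(seed)
    for i in range(n_images):
        img, ann, _meta = generate_scene(spec, seed=(int(seed) * 1_000_003 + i) % (2**31))
        if preset == "lowlight":
            pil = Image.fromarray(img)
            pil = ImageEnhance.Brightness(pil).enhance(rng.uniform(0.5, 0.9))
            pil = ImageEnhance.Contrast(pil).enhance(rng.uniform(0.6, 1.1))
            img = np.asarray(pil)
        stem = f"img_{i:05d}"
        sp = split_of[i]
        dio.write_image(out_dir / "images" / sp / f"{stem}.png", img)
        dio.write_labels(out_dir / "labels" / sp / f"{stem}.txt", ann)
    return dio.write_manifest(out_dir, names)
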