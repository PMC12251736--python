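"""Image background-complexity screening.

Separates "simple" from "complex" natural backgrounds with three image-level
metrics:

* **color histogram entropy** (bits) over a quantized RGB cube — low when
  the color distribution is concentrated;
* **color proportion** — the fraction of pixels falling in the most
  populated quantized color bin;
* **edge proportion** — Canny edge pixels over total pixels.

Decision rule: an image is *simple* if its dominant-color proportion
exceeds 60% **or** its edge proportion is below 1.5%; otherwise *complex*.
The two conditions are each stated as sufficient for "simple", so they are
combined with OR; entropy is reported for inspection but carries no
threshold of its own.

Defaults: 4x4x4 = 64 RGB bins; Canny after Gaussian smoothing
(sigma = 1) with hysteresis thresholds 100/200 on the 8-bit grayscale
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import canny

__all__ = [
    "ComplexityThresholds",
    "ComplexityReport",
    "complexity_metrics",
    "classify_background",
]


@dataclass(frozen=True)
class ComplexityThresholds:
    """Decision thresholds; both are fractions in (0, 1)."""

    color_proportion_min: float = 0.60
    edge_proportion_max: float = 0.015

    def __post_init__(self):
        for v in (self.color_proportion_min, self.edge_proportion_max):
            if not 0.0 < v < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class ComplexityReport:
    entropy_bits: float
    color_proportion: float
    edge_proportion: float
    label: str | None = None  # "simple" | "complex" | None (metrics only)


def _check_image(image) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an RGB HxWx3 image, got shape {img.shape}")
    if img.shape[0] < 8 or img.shape[1] < 8:
        raise ValueError("image too small (need at least 8x8)")
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    return img


def complexity_metrics(
    image,
    bins_per_channel: int = 4,
    canny_sigma: float = 1.0,
    canny_low: float = 100.0,
    canny_high: float = 200.0,
) -> ComplexityReport:
    """Compute the three complexity metrics (label left unset).

    ``entropy_bits = -sum p log2 p`` over the quantized color histogram;
    ``color_proportion`` is the mass of the largest bin; Canny thresholds
    are given on the 8-bit grayscale scale.
    """
    img = _check_image(image)
    n_pix = img.shape[0] * img.shape[1]

    step = 256 // bins_per_channel
    q = img // step  # (H, W, 3) bin indices
    codes = (q[..., 0].astype(np.int64) * bins_per_channel + q[..., 1]) * bins_per_channel + q[..., 2]
    counts = np.bincount(codes.ravel(), minlength=bins_per_channel**3)
    p = counts[counts > 0] / n_pix
    entropy = float(-(p * np.log2(p)).sum())
    color_prop = float(counts.max() / n_pix)

    # Hysteresis thresholds are quoted in the common OpenCV convention:
    # unnormalized Sobel response on an 8-bit image (a step of height s
    # yields a response near 4*s).  skimage's canny uses normalized Sobel
    # on [0, 1], so the conversion divides by 255 * 4.
    gray = rgb2gray(img)  # float in [0, 1]
    edges = canny(gray, sigma=canny_sigma,
                  low_threshold=canny_low / (255.0 * 4.0),
                  high_threshold=canny_high / (255.0 * 4.0))
    edge_prop = float(edges.sum() / n_pix)
    return ComplexityReport(entropy, color_prop, edge_prop)


def classify_background(
    image,
    thresholds: ComplexityThresholds = ComplexityThresholds(),
    **metric_kwargs,
) -> ComplexityReport:
    """Metrics plus the simple/complex label (OR of the two simple rules)."""
    rep = complexity_metrics(image, **metric_kwargs)
    simple = (
        rep.color_proportion > thresholds.color_proportion_min
        or rep.edge_proportion < thresholds.edge_proportion_max
    )
    return replace(rep, label="simple" if simple else "complex")
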