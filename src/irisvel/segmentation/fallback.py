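"""Classical intensity-based iris segmenter.

A CNN-free segmentation path for pipeline runs on synthetic scenes, where
the iris is a dark textured disk on bright sclera: Otsu thresholding of
the eye box, morphological cleanup, largest connected component, hole
filling.  It is a test/synthetic-data path — real eye video with makeup,
lashes, glasses or dark skin needs the trained model — and it warns and
returns an empty mask when no plausible iris-sized region is found.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu


def fallback_segment(
    frame: np.ndarray,
    eye_box: tuple[int, int, int, int],
    min_area: int = 200,
) -> np.ndarray:
    """Binary iris mask for the single eye inside ``eye_box``.

    Returns a full-frame boolean mask.  ``min_area`` (px) rejects spurious
    specks; failure to find any dark component that large yields an empty
    mask plus a warning.
    """
    f = np.asarray(frame)
    if f.ndim == 3:
        f = f[..., 0] * 0.299 + f[..., 1] * 0.587 + f[..., 2] * 0.114
    if f.dtype == np.uint8:
        f = f.astype(np.float32) / 255.0
    x0, y0, w, h = eye_box
    crop = f[y0 : y0 + h, x0 : x0 + w]
    full = np.zeros(f.shape, dtype=bool)
    if crop.size == 0:
        warnings.warn("empty eye box; returning empty mask")
        return full
    try:
        t = threshold_otsu(crop)
    except ValueError:  # constant crop
        warnings.warn("constant-intensity eye box; returning empty mask")
        return full
    dark = crop < t
    dark = ndi.binary_closing(dark, structure=np.ones((3, 3)), iterations=2)
    labels, n = ndi.label(dark)
    if n == 0:
        warnings.warn("no dark component found in eye box; returning empty mask")
        return full
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area:
        warnings.warn("largest dark component below min_area; returning empty mask")
        return full
    comp = ndi.binary_fill_holes(labels == best)
    full[y0 : y0 + h, x0 : x0 + w] = comp
    return full
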