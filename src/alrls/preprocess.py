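"""Intensity normalisation, CLAHE and patch extraction.

This is the exact pipeline feeding the patch classifier: a 10x10 window is
cut around a contour point, amplified to 32x32 by bilinear interpolation,
then contrast-enhanced with CLAHE.  Normalisation is applied once per image
(not per patch) so the two patch classes stay comparable within one image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import exposure
from skimage.transform import resize

__all__ = [
    "Patch",
    "PatchRejected",
    "normalize",
    "clahe",
    "bilinear_upsample",
    "extract_patch",
    "RAW_SIZE",
    "ENHANCED_SIZE",
    "BORDER_MARGIN",
    "CLAHE_CLIP_LIMIT",
    "CLAHE_TILE_GRID",
]

#: raw sampling window, in pixels (10x10, amplified to 32x32)
RAW_SIZE = 10
ENHANCED_SIZE = 32
#: patch centres must be at least this far from every image border
BORDER_MARGIN = 5
#: CLAHE defaults on the 32x32 patch: clip limit on the [0,1] scale and a
#: 4x4 tile grid (8x8-pixel tiles)
CLAHE_CLIP_LIMIT = 0.02
CLAHE_TILE_GRID = (4, 4)

#: class labels, in fixed (p1, p2) output order
LABEL_BOUNDARY = "boundary"
LABEL_LESION = "lesion"
LABELS = (LABEL_BOUNDARY, LABEL_LESION)


class PatchRejected(ValueError):
    """Signal that a patch centre is too close to the image border."""


@dataclass
class Patch:
    """A classifier input patch.

    ``raw`` is the 10x10 intensity window centred on ``center`` (even-size
    windows span rows ``center-5 .. center+4``); ``enhanced`` is the 32x32
    bilinearly amplified, CLAHE-processed version actually fed to the CNN.
    """

    raw: np.ndarray
    enhanced: np.ndarray
    center: tuple[int, int]
    label: str | None = field(default=None)

    def __post_init__(self) -> None:
        if self.raw.shape != (RAW_SIZE, RAW_SIZE):
            raise ValueError(f"raw patch must be {RAW_SIZE}x{RAW_SIZE}, got {self.raw.shape}")
        if self.enhanced.shape != (ENHANCED_SIZE, ENHANCED_SIZE):
            raise ValueError(
                f"enhanced patch must be {ENHANCED_SIZE}x{ENHANCED_SIZE}, got {self.enhanced.shape}"
            )
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def normalize(image: np.ndarray) -> np.ndarray:
    """Linearly rescale an image so min -> 0 and max -> 1.

    A constant image has no intensity range; it maps to all zeros with a
    warning rather than an error.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    lo, hi = float(image.min()), float(image.max())
    if hi - lo < 1e-12:
        warnings.warn("constant image: normalisation returns all zeros", stacklevel=2)
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def clahe(
    image: np.ndarray,
    clip_limit: float = CLAHE_CLIP_LIMIT,
    tile_grid: tuple[int, int] = CLAHE_TILE_GRID,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on a [0,1] image.

    ``tile_grid`` gives the number of tiles per axis.  A constant image is a
    fixed point (a flat histogram equalises to itself).
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    rows, cols = tile_grid
    if rows > h or cols > w:
        raise ValueError(f"tile grid {tile_grid} exceeds image dims {(h, w)}")
    if image.max() - image.min() < 1e-12:
        return image.copy()
    kernel = (max(1, h // rows), max(1, w // cols))
    out = exposure.equalize_adapthist(
        np.clip(image, 0.0, 1.0), kernel_size=kernel, clip_limit=clip_limit
    )
    return np.asarray(out, dtype=np.float64)


def bilinear_upsample(raw: np.ndarray, out_size: int = ENHANCED_SIZE) -> np.ndarray:
    """Bilinearly resample a patch to ``out_size`` x ``out_size``.

    Constant inputs map to constant outputs; extrema are bounded by the
    input extrema (convex combinations only).
    """
    raw = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(raw)):
        raise ValueError("patch contains non-finite values")
    return resize(
        raw,
        (out_size, out_size),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


def extract_patch(image: np.ndarray, center: tuple[int, int], label: str | None = None) -> Patch:
    """Cut and preprocess the classifier patch centred on ``center``.

    Raises :class:`PatchRejected` when the centre is closer than
    ``BORDER_MARGIN`` pixels to any image border.
    """
    image = np.asarray(image, dtype=np.float64)
    r, c = int(center[0]), int(center[1])
    h, w = image.shape
    half = RAW_SIZE // 2
    if r < half or c < half or r > h - half or c > w - half:
        raise PatchRejected(f"patch centre {center} within {BORDER_MARGIN} px of border")
    raw = image[r - half : r + half, c - half : c + half].copy()
    enhanced = clahe(np.clip(bilinear_upsample(raw), 0.0, 1.0))
    return Patch(raw=raw, enhanced=enhanced, center=(r, c), label=label)
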