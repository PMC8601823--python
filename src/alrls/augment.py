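"""Elastic and affine patch augmentation.

Elastic distortion: per-axis stochastic displacement fields with values in
[-1, 1], smoothed by a Gaussian filter and scaled by a constant intensity
factor, then bilinear resampling with border replication.  Affine
distortion: small random scale/shear/translation -- deliberately WITHOUT a
rotation component, which was tried and found unhelpful for this task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cnn import LabeledPatchSet

__all__ = ["ElasticParams", "AffineParams", "elastic_distort", "affine_distort", "augment_set"]


@dataclass(frozen=True)
class ElasticParams:
    """Elastic displacement-field parameters.

    sigma: Gaussian smoothing width of the raw U[-1,1] field (pixels);
    alpha: constant factor scaling the smoothed field (pixels of maximum
    displacement).
    """

    sigma: tuple[float, float] = (3.0, 6.0)
    alpha: tuple[float, float] = (1.0, 4.0)

    def validate(self) -> None:
        if self.sigma[0] <= 0:
            raise ValueError("sigma must be > 0")
        if self.alpha[0] < 0:
            raise ValueError("alpha must be >= 0")


@dataclass(frozen=True)
class AffineParams:
    scale: tuple[float, float] = (0.9, 1.1)
    shear_deg: tuple[float, float] = (-5.0, 5.0)
    translation: tuple[float, float] = (-2.0, 2.0)
    #: rotation disabled by default (tested, rejected); enable explicitly
    rotation_deg: tuple[float, float] = (0.0, 0.0)


def _resample(patch: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    out = ndimage.map_coordinates(patch, [rows, cols], order=1, mode="nearest")
    return np.clip(out, 0.0, 1.0)


def elastic_distort(
    patch: np.ndarray,
    params: ElasticParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Warp a [0,1] patch by a smoothed random displacement field.

    With alpha = 0 the output equals the input bit-for-bit.
    """
    params = params or ElasticParams()
    params.validate()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    patch = np.asarray(patch, dtype=np.float64)
    sigma = rng.uniform(*params.sigma)
    alpha = rng.uniform(*params.alpha)
    dr = ndimage.gaussian_filter(rng.uniform(-1, 1, patch.shape), sigma) * alpha
    dc = ndimage.gaussian_filter(rng.uniform(-1, 1, patch.shape), sigma) * alpha
    if alpha == 0:
        return patch.copy()
    h, w = patch.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    return _resample(patch, rr + dr, cc + dc)


def affine_distort(
    patch: np.ndarray,
    params: AffineParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Random small affine warp (scale, shear, translation; no rotation)."""
    params = params or AffineParams()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    patch = np.asarray(patch, dtype=np.float64)
    h, w = patch.shape
    s = rng.uniform(*params.scale)
    shear = np.deg2rad(rng.uniform(*params.shear_deg))
    rot = np.deg2rad(rng.uniform(*params.rotation_deg))
    t = rng.uniform(*params.translation, size=2)
    # map output coordinates back to input, about the patch centre
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    fwd = np.array(
        [
            [s * np.cos(rot), -s * np.sin(rot) + np.tan(shear)],
            [s * np.sin(rot), s * np.cos(rot)],
        ]
    )
    inv = np.linalg.inv(fwd)
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    coords = np.stack([rr - center[0] - t[0], cc - center[1] - t[1]])
    src = np.tensordot(inv, coords, axes=1) + center[:, None, None]
    return _resample(patch, src[0], src[1])


def augment_set(
    data: LabeledPatchSet,
    factor: int,
    seed: int = 0,
    elastic: ElasticParams | None = None,
    affine: AffineParams | None = None,
) -> LabeledPatchSet:
    """Enlarge a patch set ``factor`` times (originals retained).

    Every synthetic patch is an elastic+affine distortion of an original;
    labels are preserved, so class balance is too.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return LabeledPatchSet(X=data.X.copy(), y=data.y.copy())
    rng = np.random.default_rng(seed)
    chunks_X = [data.X.copy()]
    chunks_y = [data.y.copy()]
    for _ in range(factor - 1):
        distorted = np.empty_like(data.X)
        for i in range(len(data)):
            warped = elastic_distort(data.X[i], elastic, rng)
            distorted[i] = affine_distort(warped, affine, rng)
        chunks_X.append(distorted)
        chunks_y.append(data.y.copy())
    return LabeledPatchSet(X=np.concatenate(chunks_X), y=np.concatenate(chunks_y))
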