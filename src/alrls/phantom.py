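"""Synthetic sinus phantoms with exact ground truth.

Each phantom emulates a single axial CT slice through an air-filled sinus
cavity: a dark, irregular elliptical cavity enclosed by bright bone, with
zero or more intermediate-intensity heterogeneous lesion blobs attached to
the wall (mucosal-thickening morphology) or floating free, a smooth
multiplicative bias field, partial-volume blur and Gaussian noise.

Ground-truth convention (consequential!): ``cavity_mask`` is the FULL
cavity region including the area occluded by lesions -- the target contour
must pass through lesion edges, not stop on them.  ``lesion_mask`` is kept
separately for patch labelling.

Patch labelling: the "boundary" class is the whole cavity wall (including
arcs where a lesion touches the bone -- those are still places the contour
must stop), and the "lesion" class is the lesion/air interface inside the
cavity (where the contour must push through).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import preprocess
from .cnn import LabeledPatchSet
from .preprocess import BORDER_MARGIN, LABEL_BOUNDARY, LABEL_LESION, extract_patch

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "sample_labelled_patches",
    "generate_cohort",
    "stalling_spec",
    "clean_spec",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic sinus image."""

    shape: tuple[int, int] = (128, 128)
    #: cavity semi-axes drawn uniformly from this range (pixels)
    semi_axes_range: tuple[float, float] = (12.0, 18.0)
    #: total relative amplitude of the radial boundary harmonics
    irregularity: float = 0.05
    #: random jitter of the cavity centre around the image centre (pixels)
    center_jitter: float = 4.0
    cavity_mean: float = 0.15
    bone_mean: float = 0.85
    lesion_mean_range: tuple[float, float] = (0.55, 0.70)
    #: amplitude of the smoothed-noise texture inside lesions
    lesion_texture: float = 0.06
    n_lesions: int = 0
    lesion_radius_range: tuple[float, float] = (5.0, 8.0)
    wall_attached_prob: float = 1.0
    #: air-region CT noise is ~0.3-1% of the air/bone dynamic range
    noise_sigma: float = 0.01
    #: multiplicative low-frequency bias amplitude (sum of 2 cosine products)
    bias_amplitude: float = 0.08
    #: partial-volume blur; sub-pixel PSF at this scaled-down geometry
    blur_sigma: float = 0.4
    #: minimum margin between cavity and image border
    margin: int = 8
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.lesion_mean_range
        if not (self.cavity_mean < lo <= hi <= self.bone_mean + 0.05):
            raise ValueError(
                "intensity ordering violated: need cavity_mean < lesion means <= bone_mean"
            )
        h, w = self.shape
        reach = self.semi_axes_range[1] * (1 + self.irregularity) + self.center_jitter
        if reach + self.margin > min(h, w) / 2:
            raise ValueError(f"cavity (reach {reach:.1f}) cannot keep a {self.margin} px margin in {self.shape}")
        if self.n_lesions and self.lesion_radius_range[1] >= self.semi_axes_range[0]:
            raise ValueError("lesions must be smaller than the cavity semi-axes")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")


@dataclass
class PhantomSample:
    image: np.ndarray
    #: ground truth: FULL cavity, including lesion-occluded area
    cavity_mask: np.ndarray
    #: lesion regions (subset of the cavity)
    lesion_mask: np.ndarray
    spec: PhantomSpec
    seed: int

    @property
    def air_mask(self) -> np.ndarray:
        """The dark, air-filled part of the cavity (lesions excluded)."""
        return self.cavity_mask & ~self.lesion_mask

    @property
    def cavity_centroid(self) -> tuple[float, float]:
        """Centroid of the air region -- where an initial contour is seeded."""
        air = self.air_mask
        dist = ndimage.distance_transform_edt(air)
        # pull the seed to a deep air pixel if the plain centroid falls on
        # (or right next to) a lesion
        rr, cc = np.nonzero(air)
        r0, c0 = float(rr.mean()), float(cc.mean())
        if dist[int(round(r0)), int(round(c0))] >= 3:
            return r0, c0
        best = np.unravel_index(np.argmax(dist), dist.shape)
        return float(best[0]), float(best[1])

    def inscribed_radius(self) -> float:
        """Radius of the largest seed circle fully inside the air region."""
        dist = ndimage.distance_transform_edt(self.air_mask)
        r0, c0 = self.cavity_centroid
        return float(dist[int(round(r0)), int(round(c0))])


def _harmonic_profile(rng: np.random.Generator, amplitude: float):
    """Smooth random radial perturbation f(psi) = 1 + sum_k c_k cos(k psi + phase)."""
    ks = np.arange(2, 6)
    raw = rng.uniform(0.3, 1.0, size=ks.size)
    weights = raw / raw.sum() * amplitude
    phases = rng.uniform(0, 2 * np.pi, size=ks.size)

    def f(psi: np.ndarray) -> np.ndarray:
        out = np.ones_like(psi)
        for k, c, ph in zip(ks, weights, phases):
            out = out + c * np.cos(k * psi + ph)
        return out

    return f


def _blob_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    profile,
    axes_ratio: float = 1.0,
    theta: float = 0.0,
) -> np.ndarray:
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    dr, dc = rr - center[0], cc - center[1]
    xr = np.cos(theta) * dr + np.sin(theta) * dc
    yr = -np.sin(theta) * dr + np.cos(theta) * dc
    rho = np.hypot(xr / axes_ratio, yr)
    psi = np.arctan2(yr, xr)
    return rho <= radius * profile(psi)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Deterministically generate one phantom from ``spec`` (and its seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape

    center = (
        h / 2 + rng.uniform(-spec.center_jitter, spec.center_jitter),
        w / 2 + rng.uniform(-spec.center_jitter, spec.center_jitter),
    )
    a, b = rng.uniform(*spec.semi_axes_range, size=2)
    theta = rng.uniform(0, np.pi)
    profile = _harmonic_profile(rng, spec.irregularity)
    cavity = _blob_mask(spec.shape, center, b, profile, axes_ratio=a / b, theta=theta)

    # lesions: blobs clipped to the cavity, wall-attached by default
    lesions = np.zeros(spec.shape, dtype=bool)
    boundary_pts = None
    for _ in range(spec.n_lesions):
        radius = rng.uniform(*spec.lesion_radius_range)
        if rng.random() < spec.wall_attached_prob:
            if boundary_pts is None:
                boundary_pts = np.argwhere(cavity & ~ndimage.binary_erosion(cavity))
            pt = boundary_pts[rng.integers(len(boundary_pts))]
            lesion_center = (float(pt[0]), float(pt[1]))
        else:
            # free-floating: place well inside the cavity
            interior = np.argwhere(ndimage.binary_erosion(cavity, iterations=int(radius) + 2))
            if len(interior) == 0:
                raise ValueError("lesion larger than the cavity interior")
            pt = interior[rng.integers(len(interior))]
            lesion_center = (float(pt[0]), float(pt[1]))
        blob_profile = _harmonic_profile(rng, 0.15)
        lesions |= _blob_mask(spec.shape, lesion_center, radius, blob_profile)
    lesions &= cavity

    # piecewise-constant template, then texture, blur, bias, noise
    img = np.full(spec.shape, spec.bone_mean)
    img[cavity] = spec.cavity_mean
    labeled, n_found = ndimage.label(lesions)
    for comp in range(1, n_found + 1):
        mean = rng.uniform(*spec.lesion_mean_range)
        mask = labeled == comp
        texture = ndimage.gaussian_filter(rng.standard_normal(spec.shape), 1.5)
        texture *= spec.lesion_texture / max(texture.std(), 1e-12)
        img[mask] = mean + texture[mask]

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)

    if spec.bias_amplitude > 0:
        rr, cc = np.meshgrid(np.arange(h) / h, np.arange(w) / w, indexing="ij")
        bias = np.zeros(spec.shape)
        for _ in range(2):
            fr, fc = rng.uniform(0.5, 1.5, size=2)
            ph_r, ph_c = rng.uniform(0, 2 * np.pi, size=2)
            bias += np.cos(2 * np.pi * fr * rr + ph_r) * np.cos(2 * np.pi * fc * cc + ph_c)
        bias *= spec.bias_amplitude / 2.0
        img = img * (1.0 + bias)

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    img = np.clip(img, 0.0, 1.0)

    return PhantomSample(image=img, cavity_mask=cavity, lesion_mask=lesions, spec=spec, seed=spec.seed)


def _inner_boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def _valid_centers(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if len(points) == 0:
        return points
    h, w = shape
    m = BORDER_MARGIN
    keep = (points[:, 0] >= m) & (points[:, 0] <= h - m) & (points[:, 1] >= m) & (points[:, 1] <= w - m)
    return points[keep]


def class_center_sets(sample: PhantomSample) -> tuple[np.ndarray, np.ndarray]:
    """Candidate patch centres for (boundary, lesion) classes.

    boundary = the full cavity wall; lesion = lesion/air interface strictly
    inside the cavity (wall-contact arcs excluded -- they belong to the wall).
    """
    wall = _inner_boundary(sample.cavity_mask)
    lesion_edge = _inner_boundary(sample.lesion_mask)
    near_wall = ndimage.binary_dilation(wall, iterations=2)
    lesion_edge = lesion_edge & ~near_wall
    return (
        _valid_centers(np.argwhere(wall), sample.image.shape),
        _valid_centers(np.argwhere(lesion_edge), sample.image.shape),
    )


def sample_labelled_patches(
    sample: PhantomSample, n_per_class: int, seed: int = 0
) -> LabeledPatchSet:
    """Balanced labelled patches from one phantom's class boundary sets."""
    rng = np.random.default_rng(seed)
    image = preprocess.normalize(sample.image)
    wall_pts, lesion_pts = class_center_sets(sample)
    patches = []
    for label, pts in ((LABEL_BOUNDARY, wall_pts), (LABEL_LESION, lesion_pts)):
        if len(pts) == 0:
            warnings.warn(f"no candidate centres for class {label!r}", stacklevel=2)
            continue
        n = min(n_per_class, len(pts)) if len(pts) < n_per_class else n_per_class
        if n < n_per_class:
            warnings.warn(
                f"only {n} of {n_per_class} requested {label!r} patches available", stacklevel=2
            )
        idx = rng.choice(len(pts), size=n, replace=len(pts) < n)
        for i in idx:
            patches.append(extract_patch(image, tuple(pts[i]), label=label))
    return LabeledPatchSet.from_patches(patches)


def build_patch_dataset(
    n_per_class: int,
    n_phantoms: int = 150,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    center_jitter: int = 2,
) -> LabeledPatchSet:
    """Balanced labelled patch set pooled over many lesioned phantoms.

    Lesion-edge pixels are scarce (a few tens per phantom), so candidates
    are pooled across ``n_phantoms`` before sampling ``n_per_class``
    patches per class; sampling falls back to replacement (with a warning)
    only if the pool is still too small.  Centres are jittered by up to
    ``center_jitter`` pixels: at run time the contour queries the
    classifier from wherever it stalls, which is rarely the exact edge
    pixel, and training must cover that positional slack.
    """
    base = base_spec or stalling_spec()
    rng = np.random.default_rng(seed)
    wall_pool: list[tuple[np.ndarray, np.ndarray]] = []
    lesion_pool: list[tuple[np.ndarray, np.ndarray]] = []
    images = []
    for i in range(n_phantoms):
        spec_i = replace(base, seed=int(rng.integers(0, 2**31 - 1)))
        sample = generate_phantom(spec_i)
        image = preprocess.normalize(sample.image)
        images.append(image)
        wall_pts, lesion_pts = class_center_sets(sample)
        for pts, pool in ((wall_pts, wall_pool), (lesion_pts, lesion_pool)):
            for p in pts:
                pool.append((i, (int(p[0]), int(p[1]))))
    patches = []
    for label, pool in ((LABEL_BOUNDARY, wall_pool), (LABEL_LESION, lesion_pool)):
        if not pool:
            raise ValueError(f"no candidate centres for class {label!r} in the cohort")
        replace_flag = len(pool) < n_per_class
        if replace_flag:
            warnings.warn(
                f"class {label!r}: pool {len(pool)} < requested {n_per_class}; "
                "sampling with replacement",
                stacklevel=2,
            )
        idx = rng.choice(len(pool), size=n_per_class, replace=replace_flag)
        for j in idx:
            img_i, center = pool[j]
            if center_jitter:
                h, w = images[img_i].shape
                r = int(np.clip(center[0] + rng.integers(-center_jitter, center_jitter + 1),
                                BORDER_MARGIN, h - BORDER_MARGIN))
                c = int(np.clip(center[1] + rng.integers(-center_jitter, center_jitter + 1),
                                BORDER_MARGIN, w - BORDER_MARGIN))
                center = (r, c)
            patches.append(extract_patch(images[img_i], center, label=label))
    return LabeledPatchSet.from_patches(patches)


class GroundTruthClassifier:
    """Synthetic oracle standing in for the trained CNN in tests.

    Answers patch queries from the phantom's ground-truth masks instead of
    learned features: locations on (or just inside) a lesion/air interface
    are "lesion", locations near the cavity wall are "boundary", anything
    else is ambiguous.  Matches the classifier protocol used by the
    segmenter (``trained`` + ``predict_patch``).
    """

    trained = True

    def __init__(self, sample: PhantomSample, confidence: float = 0.95):
        self.confidence = confidence
        wall = _inner_boundary(sample.cavity_mask)
        self._near_wall = ndimage.binary_dilation(wall, iterations=2)
        lesion_zone = sample.lesion_mask & ~self._near_wall
        self._lesionish = ndimage.binary_dilation(lesion_zone, iterations=1) & ~self._near_wall

    def predict_patch(self, patch) -> tuple[float, float]:
        r, c = patch.center
        if self._near_wall[r, c]:
            return self.confidence, 1.0 - self.confidence
        if self._lesionish[r, c]:
            return 1.0 - self.confidence, self.confidence
        return 0.5, 0.5


def clean_spec(**overrides) -> PhantomSpec:
    """A lesion-free phantom specification."""
    return replace(PhantomSpec(), n_lesions=0, **overrides)


def stalling_spec(**overrides) -> PhantomSpec:
    """The failure-mode regime: large, high-contrast, wall-attached lesions
    blocking a substantial fraction of the wall, so a fixed-parameter
    localized contour stalls on lesion edges."""
    base = replace(
        PhantomSpec(),
        n_lesions=3,
        lesion_radius_range=(6.5, 9.5),
        lesion_mean_range=(0.55, 0.70),
        wall_attached_prob=1.0,
    )
    return replace(base, **overrides)


def generate_cohort(
    n_images: int,
    base_spec: PhantomSpec | None = None,
    n_lesions_range: tuple[int, int] | None = None,
    seed: int = 0,
) -> tuple[list[PhantomSample], list[dict]]:
    """Generate ``n_images`` phantoms with per-sample seeds from a master seed.

    Returns the samples and a JSON-serialisable manifest of every spec.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    manifest: list[dict] = []
    for _ in range(n_images):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec_i = replace(base, seed=sub_seed)
        if n_lesions_range is not None:
            lo, hi = n_lesions_range
            spec_i = replace(spec_i, n_lesions=int(rng.integers(lo, hi + 1)))
        samples.append(generate_phantom(spec_i))
        manifest.append(asdict(spec_i))
    return samples, manifest


def write_cohort(samples: list[PhantomSample], manifest: list[dict], outdir: str | Path) -> None:
    """Write a cohort as PNG images + masks + a JSON manifest."""
    from .io import write_image, write_mask

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        write_image(s.image, outdir / f"phantom_{i:03d}.png")
        write_mask(s.cavity_mask, outdir / f"phantom_{i:03d}_cavity.png")
        write_mask(s.lesion_mask, outdir / f"phantom_{i:03d}_lesions.png")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
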