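"""Stalled-point detection, CNN queries and speed compensation.

A contour point whose data speed stays near zero for several iterations is
either on the true sinus wall (it should stay put until convergence) or
trapped on a lesion edge (it should be pushed through).  The patch
classifier arbitrates: it outputs p1 = probability "boundary of sinus" and
p2 = probability "lesion".  Ambiguous outputs with |p1 - p2| <= 0.2 are
dropped for stability.  Compensated points receive a non-negative extra
outward (interior-growing) term

    exp(|lambda1 + lambda2|^(1/2)) * ((1 + p2)/(1 + p1) - 1/2)

added to the data integrand over their localization ball, i.e. the point
speed changes by -term * integral_B delta(phi) dy under the
positive-shrinks sign convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .config import RunConfig
from .level_set import EvolutionState, contour_points
from .preprocess import PatchRejected, extract_patch

__all__ = [
    "ClassProbabilities",
    "PointStatus",
    "StalledPoint",
    "detect_stable_points",
    "compensation_term",
    "decide_point",
    "apply_compensation",
    "classify_point",
]


@dataclass(frozen=True)
class ClassProbabilities:
    """Two-class softmax output: p1 = sinus boundary, p2 = lesion."""

    p1: float
    p2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p1 <= 1.0 and 0.0 <= self.p2 <= 1.0):
            raise ValueError(f"probabilities outside [0,1]: p1={self.p1}, p2={self.p2}")
        if abs(self.p1 + self.p2 - 1.0) > 1e-6:
            raise ValueError(f"p1 + p2 = {self.p1 + self.p2} != 1 (two-class softmax)")


class PointStatus(str, Enum):
    PENDING = "pending"
    COMPENSATED = "compensated"
    CONFIRMED_BOUNDARY = "confirmed_boundary"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class StalledPoint:
    location: tuple[int, int]
    stalled_for: int
    probs: ClassProbabilities | None = None
    status: PointStatus = PointStatus.PENDING


def detect_stable_points(
    state: EvolutionState, speed: np.ndarray, max_band_speed: float, cfg: RunConfig
) -> list[StalledPoint]:
    """Update per-site stall streaks and return currently stalled points.

    A point is "stable" when the interface velocity through it is zero: the
    zero crossing stays pinned to the same lattice site for
    ``stability_window`` consecutive iterations.  (At a blocked interface
    the pointwise data speeds are large but opposing, so the effective
    contour speed -- not the raw speed magnitude -- is the robust signal;
    a low raw speed, below ``stability_tol`` of the band maximum, counts as
    stalled too.)  Streaks of sites that leave the contour are reset.
    """
    streak = state.low_speed_streak
    pts = contour_points(state.phi)
    on_contour = np.zeros(state.phi.shape, dtype=bool)
    if len(pts):
        on_contour[pts[:, 0], pts[:, 1]] = True
    low_speed = np.abs(speed) < cfg.stability_tol * max_band_speed
    pinned = on_contour & (state.prev_contour | low_speed)
    streak[~pinned] = 0
    streak[pinned] += 1
    state.prev_contour = on_contour
    stalled_sites = np.argwhere(streak >= cfg.stability_window)
    return [
        StalledPoint(location=(int(r), int(c)), stalled_for=int(streak[r, c]))
        for r, c in stalled_sites
    ]


def compensation_term(probs: ClassProbabilities, lambda1: float, lambda2: float) -> float:
    """The probability-weighted compensation magnitude (always >= 0).

    Zero when the classifier is certain of the sinus boundary (p1=1) and
    maximal, 1.5*exp(sqrt(|l1+l2|)), when certain of a lesion (p2=1);
    strictly decreasing in p1 along p2 = 1 - p1.
    """
    return math.exp(math.sqrt(abs(lambda1 + lambda2))) * ((1.0 + probs.p2) / (1.0 + probs.p1) - 0.5)


def decide_point(point: StalledPoint, cfg: RunConfig) -> StalledPoint:
    """Apply the drop rule and the p2-vs-p1 decision to a classified point."""
    if point.probs is None:
        raise ValueError(f"point {point.location} has no classifier output")
    p1, p2 = point.probs.p1, point.probs.p2
    if abs(p1 - p2) <= cfg.ambiguity_margin:
        status = PointStatus.AMBIGUOUS
    elif p2 > p1:
        status = PointStatus.COMPENSATED
    else:
        status = PointStatus.CONFIRMED_BOUNDARY
    return replace(point, status=status)


def classify_point(
    model, image: np.ndarray, location: tuple[int, int]
) -> ClassProbabilities | None:
    """Classifier probabilities for a contour point, or None near borders.

    ``model`` is any object with a ``trained`` flag and a
    ``predict_patch(patch) -> (p1, p2)`` method (the trained CNN in
    production; a ground-truth oracle in tests).  ``image`` must already
    be normalised to [0,1]; the patch pipeline (10x10 window, bilinear
    amplification to 32x32, CLAHE) matches training exactly.
    Deterministic: CNN inference uses shadow weights and frozen batch-norm
    statistics.
    """
    if not model.trained:
        raise RuntimeError("classifier queried before training/loading")
    try:
        patch = extract_patch(image, location)
    except PatchRejected:
        return None
    p1, p2 = model.predict_patch(patch)
    # guard tiny float drift out of the softmax
    total = p1 + p2
    return ClassProbabilities(p1=p1 / total, p2=p2 / total)


def apply_compensation(
    speed: np.ndarray,
    delta_mass: np.ndarray,
    points: list[StalledPoint],
    cfg: RunConfig,
) -> np.ndarray:
    """Inject the compensation flow at compensated points.

    The term sits inside the local data integral, so the point speed gains
    -term * (Dirac mass of its ball); the sign is outward (interior
    growth).  Points with any other status are untouched.
    """
    if not points:
        return speed
    out = speed.copy()
    for pt in points:
        if pt.status is not PointStatus.COMPENSATED:
            continue
        r, c = pt.location
        term = compensation_term(pt.probs, cfg.lambda1, cfg.lambda2)
        out[r, c] = out[r, c] - term * delta_mass[r, c]
    return out
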