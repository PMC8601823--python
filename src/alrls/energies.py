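"""Localized region statistics and speed flows.

Every contour point x carries local statistics computed inside a disk
("localization ball") B(x, .): Heaviside-smoothed interior/exterior means
u_x, v_x and areas A_u, A_v.  Two data energies drive the contour:

* uniform modelling (UM): the piecewise-constant Chan-Vese residual;
* mean separation (MS): the Yezzi-style energy -(u_x - v_x)^2, minimised
  when the local means are maximally separated.

The gradient flow moves the pixel at x by the residual of ITS intensity
I(x) judged against the statistics of every contour point y in its ball
(the derivative of the means with respect to phi vanishes because the
means are least-squares optimal):

  UM speed(x) = sum_y B(x,y) delta(phi_y) [l1 (I_x-u_y)^2 - l2 (I_x-v_y)^2]
  MS speed(x) = sum_y B(x,y) delta(phi_y) [l2 (I_x-u_y)^2/A_u(y)
                                           - l1 (I_x-v_y)^2/A_v(y)]

signed so that a POSITIVE speed shrinks the interior under the
interior-negative phi convention: a dark pixel surrounded by contour
points whose exteriors look bright gets a negative speed and is claimed.
In the global-ball limit the UM flow reduces exactly to the global
Chan-Vese force field.

The per-point functions are the reference semantics; ``evolution_fields``
evaluates the identical quantities for every pixel at once through FFT
disk convolutions (zero padding outside the image reproduces the
border-clipped ball).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as _fft

from .config import RunConfig
from .level_set import dirac, gradient_magnitude, heaviside

__all__ = [
    "LocalBall",
    "LocalStats",
    "ball_mask",
    "local_stats",
    "um_speed",
    "ms_speed",
    "SpeedFields",
    "speed_fields",
    "energy_value",
    "DEGENERATE_AREA",
]

#: areas below this count as degenerate (all-interior or all-exterior ball)
DEGENERATE_AREA = 1e-8


@dataclass
class LocalBall:
    """A disk neighbourhood clipped to the image."""

    center: tuple[int, int]
    radius: int
    #: bounding-box slices into the image
    rows: slice
    cols: slice
    #: disk footprint within the bounding box
    mask: np.ndarray


def ball_mask(center: tuple[int, int], radius: int, image_shape: tuple[int, int]) -> LocalBall:
    """Disk of ``radius`` pixels around ``center``, clipped to the image."""
    if radius < 1:
        raise ValueError(f"ball radius must be >= 1, got {radius}")
    r, c = int(center[0]), int(center[1])
    h, w = image_shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"ball centre {center} outside image {image_shape}")
    r0, r1 = max(0, r - radius), min(h, r + radius + 1)
    c0, c1 = max(0, c - radius), min(w, c + radius + 1)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    mask = (rr - r) ** 2 + (cc - c) ** 2 <= radius * radius
    return LocalBall(center=(r, c), radius=int(radius), rows=slice(r0, r1), cols=slice(c0, c1), mask=mask)


@dataclass
class LocalStats:
    """Local interior/exterior means and smoothed areas inside one ball."""

    u_x: float
    v_x: float
    A_u: float
    A_v: float

    @property
    def degenerate(self) -> bool:
        return self.A_u < DEGENERATE_AREA or self.A_v < DEGENERATE_AREA


def local_stats(image: np.ndarray, phi: np.ndarray, ball: LocalBall, eps: float) -> LocalStats:
    """Heaviside-smoothed interior/exterior means within one ball."""
    img = image[ball.rows, ball.cols][ball.mask]
    h_int = heaviside(phi[ball.rows, ball.cols][ball.mask], eps)
    a_u = float(np.sum(h_int))
    a_v = float(np.sum(1.0 - h_int))
    u_x = float(np.sum(h_int * img) / a_u) if a_u >= DEGENERATE_AREA else 0.0
    v_x = float(np.sum((1.0 - h_int) * img) / a_v) if a_v >= DEGENERATE_AREA else 0.0
    return LocalStats(u_x=u_x, v_x=v_x, A_u=a_u, A_v=a_v)


def um_speed(image: np.ndarray, phi: np.ndarray, x: tuple[int, int], cfg: RunConfig) -> float:
    """Localized uniform-modelling (Chan-Vese) data speed at point x.

    The pixel at x is judged against the local interior/exterior means of
    every contour point y inside its ball:
    sum_y B(x,y) delta(phi_y) [l1 (I_x - u_y)^2 - l2 (I_x - v_y)^2].
    Positive speed shrinks the interior.
    """
    ball = ball_mask(x, cfg.ball_radius, image.shape)
    eps = cfg.epsilon_heaviside
    ix = float(image[x[0], x[1]])
    total = 0.0
    rows = range(ball.rows.start, ball.rows.stop)
    sub_mask = ball.mask
    for i, r in enumerate(rows):
        for j, c in enumerate(range(ball.cols.start, ball.cols.stop)):
            if not sub_mask[i, j]:
                continue
            dl = float(dirac(phi[r, c], eps))
            if dl == 0.0:
                continue
            st = local_stats(image, phi, ball_mask((r, c), cfg.ball_radius, image.shape), eps)
            if st.degenerate:
                continue
            total += dl * (
                cfg.lambda1 * (ix - st.u_x) ** 2 - cfg.lambda2 * (ix - st.v_x) ** 2
            )
    return float(total)


def ms_speed(image: np.ndarray, phi: np.ndarray, x: tuple[int, int], cfg: RunConfig) -> float:
    """Localized mean-separation data speed at point x.

    As :func:`um_speed` but each neighbour's residuals are divided by its
    local areas: sum_y B delta(phi_y) [l2 (I_x-u_y)^2/A_u(y)
    - l1 (I_x-v_y)^2/A_v(y)].
    """
    ball = ball_mask(x, cfg.ball_radius, image.shape)
    eps = cfg.epsilon_heaviside
    ix = float(image[x[0], x[1]])
    total = 0.0
    for i, r in enumerate(range(ball.rows.start, ball.rows.stop)):
        for j, c in enumerate(range(ball.cols.start, ball.cols.stop)):
            if not ball.mask[i, j]:
                continue
            dl = float(dirac(phi[r, c], eps))
            if dl == 0.0:
                continue
            st = local_stats(image, phi, ball_mask((r, c), cfg.ball_radius, image.shape), eps)
            if st.degenerate:
                continue
            total += dl * (
                cfg.lambda2 * (ix - st.u_x) ** 2 / st.A_u
                - cfg.lambda1 * (ix - st.v_x) ** 2 / st.A_v
            )
    return float(total)


# ---------------------------------------------------------------------------
# whole-field evaluation via FFT disk convolutions


class _DiskConvolver:
    """Caches the kernel FFT for repeated disk convolutions on one shape."""

    def __init__(self, shape: tuple[int, int], radius: int):
        self.shape = shape
        self.radius = radius
        h, w = shape
        d = 2 * radius + 1
        yy, xx = np.meshgrid(np.arange(d) - radius, np.arange(d) - radius, indexing="ij")
        kernel = (yy * yy + xx * xx <= radius * radius).astype(np.float64)
        self._fshape = (_fft.next_fast_len(h + d - 1), _fft.next_fast_len(w + d - 1))
        self._kf = _fft.rfft2(kernel, self._fshape)

    def __call__(self, a: np.ndarray) -> np.ndarray:
        h, w = self.shape
        r = self.radius
        full = _fft.irfft2(_fft.rfft2(a, self._fshape) * self._kf, self._fshape)
        return full[r : r + h, r : r + w]


_conv_cache: dict[tuple[tuple[int, int], int], _DiskConvolver] = {}


def _disk_conv(shape: tuple[int, int], radius: int) -> _DiskConvolver:
    key = (shape, radius)
    if key not in _conv_cache:
        _conv_cache[key] = _DiskConvolver(shape, radius)
    return _conv_cache[key]


@dataclass
class SpeedFields:
    """Per-pixel localized statistics, speeds and energy integrand."""

    u: np.ndarray
    v: np.ndarray
    A_u: np.ndarray
    A_v: np.ndarray
    #: Dirac mass of the ball, integral of delta(phi) over B(x,.)
    delta_mass: np.ndarray
    #: data speed of the configured energy model (positive shrinks interior)
    speed: np.ndarray
    degenerate: np.ndarray
    #: pointwise integrand of the traced energy (data + mu * length)
    energy_integrand: np.ndarray


def static_moments(image: np.ndarray, cfg: RunConfig) -> dict[str, np.ndarray]:
    """Phi-independent ball moments of the image (cache once per run)."""
    conv = _disk_conv(image.shape, cfg.ball_radius)
    return {
        "K1": conv(np.ones_like(image)),
        "KI": conv(image),
        "KI2": conv(image * image),
    }


def evolution_fields(
    image: np.ndarray,
    phi: np.ndarray,
    cfg: RunConfig,
    static: dict[str, np.ndarray] | None = None,
) -> SpeedFields:
    """Localized data speed and energy integrand at every pixel at once.

    Identical (to FFT roundoff) to calling :func:`um_speed` / :func:`ms_speed`
    pixel by pixel.  The traced energy integrand is, per contour point, the
    local Chan-Vese residual (UM) or -(u_x - v_x)^2 (MS; more separation =
    lower energy), Dirac-weighted, plus mu times the Dirac-weighted contour
    length density.
    """
    conv = _disk_conv(image.shape, cfg.ball_radius)
    eps = cfg.epsilon_heaviside
    H = np.asarray(heaviside(phi, eps))
    D = np.asarray(dirac(phi, eps))
    static = static or static_moments(image, cfg)
    K1, KI, KI2 = static["K1"], static["KI"], static["KI2"]

    A_u = conv(H)
    Bu = conv(H * image)
    Cu = conv(H * image * image)
    A_v = np.maximum(K1 - A_u, 0.0)
    Bv = KI - Bu

    degen = (A_u < DEGENERATE_AREA) | (A_v < DEGENERATE_AREA)
    safe_Au = np.maximum(A_u, DEGENERATE_AREA)
    safe_Av = np.maximum(A_v, DEGENERATE_AREA)
    u = Bu / safe_Au
    v = Bv / safe_Av

    # flow at pixel x: the residual of I(x) judged against the local means
    # u_y, v_y of every contour point y in its ball,
    #   sum_y B(x,y) delta(phi_y) * [l1 (I_x - u_y)^2 - l2 (I_x - v_y)^2]
    # (UM; MS divides the terms by the neighbours' areas A_u(y), A_v(y)).
    # Expanded in convolved Dirac-weighted moments of the u/v fields so the
    # whole field costs a handful of FFT convolutions.
    Dm = np.where(degen, 0.0, D)
    if cfg.energy_model == "UM":
        S0 = conv(Dm)
        Su1 = conv(Dm * u)
        Su2 = conv(Dm * u * u)
        Sv1 = conv(Dm * v)
        Sv2 = conv(Dm * v * v)
        I2 = image * image
        res_u = I2 * S0 - 2.0 * image * Su1 + Su2
        res_v = I2 * S0 - 2.0 * image * Sv1 + Sv2
        speed = cfg.lambda1 * res_u - cfg.lambda2 * res_v
        e_u = Cu - 2.0 * u * Bu + u * u * A_u
        e_v = (KI2 - Cu) - 2.0 * v * Bv + v * v * A_v
        f_local = cfg.lambda1 * e_u + cfg.lambda2 * e_v
        S0_plain = S0
    else:
        wu = Dm / safe_Au
        wv = Dm / safe_Av
        T0u = conv(wu)
        T1u = conv(wu * u)
        T2u = conv(wu * u * u)
        T0v = conv(wv)
        T1v = conv(wv * v)
        T2v = conv(wv * v * v)
        I2 = image * image
        res_u = I2 * T0u - 2.0 * image * T1u + T2u
        res_v = I2 * T0v - 2.0 * image * T1v + T2v
        speed = cfg.lambda2 * res_u - cfg.lambda1 * res_v
        f_local = -((u - v) ** 2)
        S0_plain = conv(Dm)

    length = D * gradient_magnitude(phi)
    integrand = D * f_local + cfg.mu * length
    return SpeedFields(
        u=u, v=v, A_u=A_u, A_v=A_v, delta_mass=S0_plain, speed=speed, degenerate=degen,
        energy_integrand=integrand,
    )


def speed_fields(image: np.ndarray, phi: np.ndarray, cfg: RunConfig) -> SpeedFields:
    """Alias of :func:`evolution_fields` without a static-moment cache."""
    return evolution_fields(image, phi, cfg)


def energy_value(
    image: np.ndarray, phi: np.ndarray, cfg: RunConfig, band: np.ndarray | None = None
) -> float:
    """Discrete localized energy used for the convergence trace."""
    integrand = evolution_fields(image, phi, cfg).energy_integrand
    if band is not None:
        return float(np.sum(integrand[band]))
    return float(np.sum(integrand))
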