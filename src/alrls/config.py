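"""Run configuration for the level-set segmenter.

A single flat key/value document (YAML) drives a run.  Unknown keys are an
error so that typos fail loudly rather than silently falling back to a
default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


ENERGY_MODELS = ("UM", "MS")


@dataclass
class RunConfig:
    """Parameters of one segmentation run.

    The energy weights follow the usual region-based active-contour
    parameterisation: ``mu`` scales the curvature (length) regularisation,
    ``lambda1``/``lambda2`` weight the interior/exterior data residuals.
    Defaults mu=0.05, lambda1=lambda2=1.0 are the values reported to work
    best on sinus CT.
    """

    energy_model: str = "MS"
    mu: float = 0.05
    lambda1: float = 1.0
    lambda2: float = 1.0
    #: localization-ball radius in pixels; must be large enough that a ball
    #: centred on the smallest initial contour reaches the cavity wall.
    ball_radius: int = 15
    #: half-width of the narrow band, in pixels of |phi|.
    band_width: float = 8.0
    #: smoothing width of the regularised Heaviside/Dirac pair, in pixels.
    epsilon_heaviside: float = 1.5
    #: CFL number: the fastest point moves dt_cfl pixels per iteration.
    dt_cfl: float = 0.45
    max_iters: int = 400
    #: a contour point is "stalled" when its |data speed| stays below
    #: stability_tol * (max band speed) for stability_window iterations.
    stability_tol: float = 0.15
    stability_window: int = 5
    #: trailing-window relative energy change below which the run stops.
    convergence_tol: float = 1e-4
    convergence_window: int = 10
    compensation_enabled: bool = False
    #: drop rule: classifier output with |p1 - p2| <= margin is ignored.
    ambiguity_margin: float = 0.2
    #: weight of the signed-distance regularisation step.
    sdf_weight: float = 0.2
    #: phi saturation: the field is clipped to [-phi_cap, phi_cap], bounding
    #: the cliffs the regulariser must smooth (binary-level-set style).
    #: Must exceed epsilon_heaviside so the mollifier support stays free.
    phi_cap: float = 2.0
    #: regularisation sub-steps per evolution iteration; more sub-steps keep
    #: |grad phi| closer to 1 while the contour is moving fast.
    sdf_substeps: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bad: list[str] = []
        if self.energy_model not in ENERGY_MODELS:
            bad.append(f"energy_model={self.energy_model!r} (must be UM or MS)")
        if self.mu < 0:
            bad.append(f"mu={self.mu} (must be >= 0)")
        if self.lambda1 <= 0:
            bad.append(f"lambda1={self.lambda1} (must be > 0)")
        if self.lambda2 <= 0:
            bad.append(f"lambda2={self.lambda2} (must be > 0)")
        if self.ball_radius < 1:
            bad.append(f"ball_radius={self.ball_radius} (must be >= 1)")
        if self.band_width < 1:
            bad.append(f"band_width={self.band_width} (must be >= 1)")
        if self.epsilon_heaviside <= 0:
            bad.append(f"epsilon_heaviside={self.epsilon_heaviside} (must be > 0)")
        if not 0 < self.ambiguity_margin < 1:
            bad.append(f"ambiguity_margin={self.ambiguity_margin} (must be in (0,1))")
        if self.max_iters < 1:
            bad.append(f"max_iters={self.max_iters} (must be >= 1)")
        if self.stability_window < 1:
            bad.append(f"stability_window={self.stability_window} (must be >= 1)")
        if not 0 < self.sdf_weight < 0.25:
            bad.append(f"sdf_weight={self.sdf_weight} (must be in (0, 0.25))")
        if self.phi_cap <= self.epsilon_heaviside:
            bad.append(
                f"phi_cap={self.phi_cap} (must exceed epsilon_heaviside={self.epsilon_heaviside})"
            )
        if bad:
            raise ConfigError("invalid configuration: " + "; ".join(bad))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, values: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(values) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
        return cls(**values)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a flat YAML document, filling defaults."""
    with open(path, "r") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} is not a flat key/value document")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
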