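"""Simulation and pipeline configuration.

The defaults describe the volumetric brainstem imaging preparation this
package emulates: a 509.12 x 509.12 x 320 um field sampled as five planes of
512 x 512 pixels at 1.25 volumes/s, with ~2,800 nuclear-labelled neurons per
experiment. Organ-responsive neurons occupy Gaussian spatial domains whose
centroids are offset by tens of micrometres (stomach vs duodenum ~60 um),
~90% of responders are tuned to a single organ, and a configurable fraction
of responders to one organ are cross-inhibited by simultaneous stimulation
of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class OrganSpec:
    """One organ's responder population and spatial domain."""

    label: str
    centroid_um: tuple[float, float]  # in-plane (x, y) domain centre
    spread_um: float = 25.0  # isotropic Gaussian SD of the domain
    weight: float = 1.0  # relative share of responders
    ec50: float | None = None  # half-max stimulus intensity; None -> median
    hill_n: float = 1.5  # dose-response steepness

    def __post_init__(self) -> None:
        if self.spread_um <= 0:
            raise ValueError("spread_um must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass
class SuppressionSpec:
    """Cross-inhibition: a fraction of `suppressed_organ` responders lose
    `strength` (dose-scaled) of their response when `suppressor_organ` is
    stimulated simultaneously."""

    suppressed_organ: str
    suppressor_organ: str
    fraction: float
    strength: float

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")
        if not 0 < self.strength <= 1:
            raise ValueError("strength must be in (0, 1]")


def default_organs() -> list[OrganSpec]:
    # Domain centroids: duodenum offset ~60 um medially from stomach; larynx
    # rostrolateral. Weights follow the observed responder shares (stomach
    # dominating, then duodenum, then larynx).
    return [
        OrganSpec("stomach", (250.0, 250.0), weight=0.72),
        OrganSpec("duodenum", (310.0, 250.0), weight=0.23),
        OrganSpec("larynx", (180.0, 170.0), weight=0.05),
    ]


def default_suppression() -> list[SuppressionSpec]:
    return [
        SuppressionSpec("duodenum", "stomach", fraction=0.29, strength=0.8),
        SuppressionSpec("stomach", "duodenum", fraction=0.174, strength=0.8),
    ]


@dataclass
class SimConfig:
    """Full parameterization of one synthetic experiment (one FOV)."""

    n_neurons: int = 2800
    fov_um: tuple[float, float, float] = (509.12, 509.12, 320.0)
    n_planes: int = 5
    frame_rate_hz: float = 1.25
    organs: list[OrganSpec] = field(default_factory=default_organs)

    frac_responsive: float = 0.40  # neurons responding to >=1 organ
    frac_selective: float = 0.90  # of responders: single-organ tuning
    frac_multi: float = 0.10  # of responders: multi-organ tuning
    frac_rapid: float = 0.56  # of responders: rapidly adapting kinetics

    # indicator / response kinetics (seconds)
    kernel_rise_s: float = 0.3
    kernel_decay_s: float = 1.5
    adapt_tau_s: float = 10.0  # rapid-class relaxation during the stimulus

    # response amplitudes (dF/F), lognormal over responders
    amplitude_median: float = 0.6
    amplitude_sigma: float = 0.35
    # secondary-organ amplitude of multi-tuned neurons, as a uniform fraction
    # of the dominant amplitude (multi-tuned neurons respond more strongly to
    # one organ)
    multi_secondary_range: tuple[float, float] = (0.4, 0.9)

    noise_sd: float = 0.05  # dF/F units, per frame
    drift_rate: float = 0.02  # fractional photobleaching per minute
    baseline_au: tuple[float, float] = (100.0, 200.0)  # raw F baseline range

    suppression: list[SuppressionSpec] = field(default_factory=default_suppression)

    # rendering
    image_shape: tuple[int, int] = (512, 512)
    nucleus_sigma_px: float = 2.0
    background_au: float = 20.0
    pixel_noise_sd: float = 2.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be non-negative")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if any(e <= 0 for e in self.fov_um):
            raise ValueError("fov_um extents must be positive")
        for name in ("frac_responsive", "frac_selective", "frac_multi", "frac_rapid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(self.frac_selective + self.frac_multi - 1.0) > 1e-9:
            raise ValueError("frac_selective + frac_multi must sum to 1 over responders")
        if not self.organs:
            raise ValueError("at least one organ must be configured")

    # ---------------------------------------------------------------- helpers
    @property
    def pixel_size_um(self) -> tuple[float, float]:
        return (
            self.fov_um[0] / self.image_shape[1],  # x <-> columns
            self.fov_um[1] / self.image_shape[0],  # y <-> rows
        )

    @property
    def plane_spacing_um(self) -> float:
        return self.fov_um[2] / self.n_planes

    def organ_map(self) -> dict[str, OrganSpec]:
        return {o.label: o for o in self.organs}

    # -------------------------------------------------------------------- I/O
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["organs"] = [OrganSpec(**o) for o in raw.get("organs", [])]
        raw["suppression"] = [SuppressionSpec(**s) for s in raw.get("suppression", [])]
        for key in ("fov_um", "baseline_au", "multi_secondary_range", "image_shape"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        for o in raw["organs"]:
            o.centroid_um = tuple(o.centroid_um)
        return cls(**raw)
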