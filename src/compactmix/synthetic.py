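"""Seeded synthetic data generation for testing the full pipeline.

Emulates a typical compaction study: flat-faced 13 mm tablets at a target
weight of 0.5 g, prepared over a porosity range of 0.10-0.30 with three
replicate tablets per porosity level. Strength scatter is multiplicative
lognormal (tensile-strength noise scales with magnitude in diametral
compression data); dimensional measurement error is additive Gaussian.

The default material pair is the discriminative regime for model
comparison: one strongly bonding component (sigma0 = 10 MPa scale) and one
weak component at a strength ratio of roughly 10-15x over the studied
porosities. Mixtures of components with similar strengths make all mixing
rules converge and cannot distinguish them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .compactibility import CompactPoint, TabletMeasurement
from .evaluation import MeasuredMixture
from .exceptions import ConfigurationError
from .mixture_models import (
    Composition,
    interaction_predict,
    linear_rule,
    mixture_true_density,
    power_law,
)

__all__ = [
    "MaterialTruth",
    "GeneratorSpec",
    "generate_pure_component_points",
    "generate_pure_component_tablets",
    "generate_mixture_dataset",
]

_TABLET_DIAMETER_MM = 13.0
_TABLET_WEIGHT_G = 0.5


@dataclass(frozen=True)
class MaterialTruth:
    """Ground-truth R-D parameters and true density for one material."""

    sigma0: float  # MPa
    k: float  # dimensionless
    true_density: float = 1.5  # g/cm^3

    def __post_init__(self):
        if self.sigma0 <= 0 or self.k <= 0 or self.true_density <= 0:
            raise ConfigurationError("sigma0, k and true_density must be > 0")

    def strength(self, porosity: float) -> float:
        return self.sigma0 * math.exp(-self.k * porosity)


def _default_materials() -> dict[str, MaterialTruth]:
    return {
        "strong": MaterialTruth(sigma0=10.0, k=8.0, true_density=1.5),
        "weak": MaterialTruth(sigma0=1.0, k=9.0, true_density=1.6),
    }


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of a synthetic compaction study.

    ``strength_noise_sd`` is the standard deviation of the lognormal
    multiplicative noise on tensile strength (0 = noiseless);
    ``dimension_noise_sd`` is the additive Gaussian sd on diameter and
    thickness in mm. Identical seeds give identical output.
    """

    materials: Mapping[str, MaterialTruth] = field(default_factory=_default_materials)
    porosity_grid: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25, 0.30)
    replicates: int = 3
    strength_noise_sd: float = 0.05
    dimension_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.strength_noise_sd < 0 or self.dimension_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if not all(0.0 <= e < 1.0 for e in self.porosity_grid):
            raise ConfigurationError("porosity grid must lie in [0, 1)")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def _noisy_strengths(rng, true_sigma: np.ndarray, sd: float) -> np.ndarray:
    if sd == 0.0:
        return true_sigma.copy()
    return true_sigma * rng.lognormal(mean=0.0, sigma=sd, size=true_sigma.shape)


def generate_pure_component_points(
    spec: GeneratorSpec,
) -> dict[str, list[CompactPoint]]:
    """Generate (porosity, strength) points per material from R-D truth.

    sigma = sigma0 * exp(-k * eps) * lognormal noise, one value per
    replicate per porosity level. Deterministic under the spec's seed.
    """
    out: dict[str, list[CompactPoint]] = {}
    for stream, (mid, mat) in enumerate(sorted(spec.materials.items())):
        rng = spec.rng(stream=stream)
        eps = np.repeat(np.asarray(spec.porosity_grid, dtype=float), spec.replicates)
        sigma = _noisy_strengths(
            rng, np.array([mat.strength(e) for e in eps]), spec.strength_noise_sd
        )
        out[mid] = [CompactPoint(float(e), float(s)) for e, s in zip(eps, sigma)]
    return out


def generate_pure_component_tablets(
    spec: GeneratorSpec,
) -> dict[str, list[TabletMeasurement]]:
    """Generate raw tablet measurement tables per material.

    Tablet thickness is solved from the target porosity at fixed diameter
    and weight; the failure force is back-computed from the noisy R-D
    strength so that downstream porosity/strength recovery reproduces the
    generating curve up to noise.
    """
    out: dict[str, list[TabletMeasurement]] = {}
    for stream, (mid, mat) in enumerate(sorted(spec.materials.items())):
        rng = spec.rng(stream=1000 + stream)
        tablets = []
        for eps in spec.porosity_grid:
            for _ in range(spec.replicates):
                # thickness (mm) giving the target porosity: solid volume /
                # (1 - eps) = envelope volume = pi D^2 t / 4 (in cm^3)
                solid_cm3 = _TABLET_WEIGHT_G / mat.true_density
                t_mm = solid_cm3 / (1.0 - eps) * 4000.0 / (
                    math.pi * _TABLET_DIAMETER_MM**2
                )
                d_mm = _TABLET_DIAMETER_MM
                if spec.dimension_noise_sd > 0:
                    d_mm += rng.normal(0.0, spec.dimension_noise_sd)
                    t_mm += rng.normal(0.0, spec.dimension_noise_sd)
                sigma = float(
                    _noisy_strengths(
                        rng, np.array([mat.strength(eps)]), spec.strength_noise_sd
                    )[0]
                )
                force = sigma * math.pi * d_mm * t_mm / 2.0
                tablets.append(
                    TabletMeasurement(
                        weight=_TABLET_WEIGHT_G,
                        diameter=d_mm,
                        thickness=t_mm,
                        failure_force=force,
                        true_density=mat.true_density,
                    )
                )
        out[mid] = tablets
    return out


def _truth_predict(model: str, order: int | None, comp, sigma):
    if model == "interaction":
        return interaction_predict(order, comp, sigma)
    if model == "linear":
        return linear_rule(comp, sigma)
    if model == "power":
        return power_law(comp, sigma)
    raise ConfigurationError(
        f"unsupported truth model {model!r}; expected interaction, linear or power"
    )


def generate_mixture_dataset(
    spec: GeneratorSpec,
    compositions: Sequence[Sequence[float]] = ((0.75, 0.25), (0.5, 0.5), (0.25, 0.75)),
    truth_model: str = "interaction",
    truth_order: int = 4,
    material_ids: Sequence[str] | None = None,
) -> list[MeasuredMixture]:
    """Simulate measured mixture data under a chosen ground-truth model.

    For each composition x porosity x replicate, the measured strength is
    the truth model's prediction from the noiseless component R-D curves,
    times lognormal noise. Default compositions are the standard 75-25,
    50-50 and 25-75 volume-fraction ratios.
    """
    if material_ids is None:
        material_ids = tuple(sorted(spec.materials))
    mats = [spec.materials[mid] for mid in material_ids]
    mixtures = []
    for ci, vfracs in enumerate(compositions):
        if len(vfracs) != len(material_ids):
            raise ConfigurationError(
                f"composition {vfracs!r} does not match materials {material_ids!r}"
            )
        comp = Composition(components=tuple(zip(material_ids, vfracs)))
        rng = spec.rng(stream=2000 + ci)
        eps_all, sig_all = [], []
        for eps in spec.porosity_grid:
            sigma_pure = [m.strength(eps) for m in mats]
            truth = _truth_predict(truth_model, truth_order, comp, sigma_pure)
            noisy = _noisy_strengths(
                rng, np.full(spec.replicates, truth), spec.strength_noise_sd
            )
            eps_all.extend([eps] * spec.replicates)
            sig_all.extend(noisy.tolist())
        label = "-".join(f"{mid}{v:g}" for mid, v in comp.components)
        mixtures.append(
            MeasuredMixture(
                mixture_id=label,
                composition=comp,
                porosities=tuple(float(e) for e in eps_all),
                strengths=tuple(float(s) for s in sig_all),
            )
        )
    return mixtures


def mixture_density_table(spec: GeneratorSpec, weights: Sequence[float],
                          material_ids: Sequence[str] | None = None) -> float:
    """Convenience: true density of a weight-basis mixture of spec materials."""
    if material_ids is None:
        material_ids = tuple(sorted(spec.materials))
    rhos = [spec.materials[mid].true_density for mid in material_ids]
    return mixture_true_density(weights, rhos)
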