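"""Mixing rules for the tensile strength of compacted powder mixtures.

The central model treats tablet failure as the breakage of interaction
clusters of ``n`` particles (the interaction order). Under random mixing,
the probability of a cluster containing k_j particles of component j is
multinomial in the volume fractions, and the strength of that cluster is
the geometric mean of the component strengths (the Berthelot rule applied
particle-wise):

    sigma_mix = sum over cluster types  [ n! / prod(k_j!) * prod(V_j^k_j) ]
                                        * prod(sigma_j^(k_j / n))

For a binary mixture this is the binomial form

    sigma_mix = sum_{i=0..n} C(n, i) V_A^(n-i) V_B^i (sigma_A^(n-i) sigma_B^i)^(1/n)

n = 2 is the classical pairwise assumption; n -> infinity recovers the
power law (all-adhesive geometric mixing); the linear mixing rule
sigma_mix = sum V_i sigma_i is the pairwise model with arithmetic-mean
adhesive strength. Probabilities and geometric means are computed in log
space so that large orders (hundreds) remain evaluable.

Classical comparators — the linear rule, the power law, and the four
RD-combination rules that mix Ryshkewitch-Duckworth parameters (sigma0,
k) linearly (L) or geometrically (P) — are provided on the same call
signatures for side-by-side evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .compactibility import CompactibilityProfile, predict_rd
from .exceptions import CompositionError, ConfigurationError

__all__ = [
    "Composition",
    "ClusterType",
    "ClusterDistribution",
    "MixturePrediction",
    "volume_fractions",
    "mixture_true_density",
    "cluster_distribution",
    "interaction_predict",
    "linear_rule",
    "power_law",
    "rd_combination_predict",
    "predict_mixture_profile",
    "DEFAULT_ORDER",
    "RD_VARIANTS",
]

#: Default interaction order: four-particle clusters give the most accurate
#: predictions across diverse binary and multicomponent mixtures.
DEFAULT_ORDER = 4

RD_VARIANTS = ("LL", "LP", "PL", "PP")

_NORMALIZATION_TOL = 1e-6


@dataclass(frozen=True)
class Composition:
    """A mixture's per-component volume fractions, normalized to sum to 1.

    ``components`` is an ordered tuple of (material_id, volume_fraction).
    Inputs whose fractions deviate from 1 by more than 1e-6 are rejected
    rather than silently rescaled; within tolerance they are renormalized
    exactly. ``weight_fractions``/``true_densities`` record the originating
    weight-basis specification when the composition was derived from one.
    """

    components: tuple[tuple[str, float], ...]
    weight_fractions: tuple[float, ...] | None = None
    true_densities: tuple[float, ...] | None = None

    def __post_init__(self):
        comps = tuple((str(mid), float(v)) for mid, v in self.components)
        if not comps:
            raise CompositionError("composition must have at least one component")
        if any(v < 0 for _, v in comps):
            raise CompositionError("volume fractions must be >= 0")
        total = sum(v for _, v in comps)
        if abs(total - 1.0) > _NORMALIZATION_TOL:
            raise CompositionError(
                f"volume fractions sum to {total!r}, not 1 (tolerance 1e-6)"
            )
        comps = tuple((mid, v / total) for mid, v in comps)
        object.__setattr__(self, "components", comps)

    @property
    def material_ids(self) -> tuple[str, ...]:
        return tuple(mid for mid, _ in self.components)

    @property
    def volume_fractions(self) -> np.ndarray:
        return np.array([v for _, v in self.components], dtype=float)

    def __len__(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class ClusterType:
    """One cluster composition: counts k_j of each component, order n = sum k_j."""

    counts: tuple[int, ...]

    def __post_init__(self):
        if any(int(k) != k or k < 0 for k in self.counts):
            raise CompositionError("cluster counts must be non-negative integers")
        object.__setattr__(self, "counts", tuple(int(k) for k in self.counts))

    @property
    def order(self) -> int:
        return sum(self.counts)

    @property
    def is_cohesive(self) -> bool:
        """True when the cluster contains particles of a single component."""
        return sum(1 for k in self.counts if k > 0) == 1


@dataclass(frozen=True)
class ClusterDistribution:
    """All cluster types of one order with probabilities and strengths.

    ``entries`` holds (ClusterType, probability, cluster_strength_MPa); for
    m components and order n there are C(n+m-1, m-1) entries and the
    probabilities sum to 1.
    """

    order: int
    entries: tuple[tuple[ClusterType, float, float], ...]

    def expected_strength(self) -> float:
        """Probability-weighted mean cluster strength (the mixture prediction)."""
        return float(sum(p * s for _, p, s in self.entries))

    def cohesive_fraction(self) -> float:
        """Total probability of purely cohesive (single-component) clusters."""
        return float(sum(p for ct, p, _ in self.entries if ct.is_cohesive))


@dataclass(frozen=True)
class MixturePrediction:
    """A predicted compactibility profile for a mixture under one model."""

    model_id: str
    porosities: tuple[float, ...]
    strengths: tuple[float, ...]

    def __post_init__(self):
        if len(self.porosities) != len(self.strengths):
            raise ConfigurationError("porosity and strength grids differ in length")


def _check_weights_densities(weights, densities):
    w = np.asarray(weights, dtype=float)
    rho = np.asarray(densities, dtype=float)
    if w.shape != rho.shape or w.ndim != 1:
        raise CompositionError(
            f"weights and densities must be equal-length 1-D, got {w.shape} vs {rho.shape}"
        )
    if np.any(w < 0):
        raise CompositionError("weight fractions must be >= 0")
    if abs(w.sum() - 1.0) > _NORMALIZATION_TOL:
        raise CompositionError(f"weight fractions sum to {w.sum()!r}, not 1")
    if np.any(rho <= 0):
        raise CompositionError("true densities must be > 0")
    return w, rho


def volume_fractions(
    weights: Sequence[float],
    densities: Sequence[float],
    material_ids: Sequence[str] | None = None,
) -> Composition:
    """Convert weight fractions to volume fractions via true densities.

    V_i = (w_i / rho_i) / sum_j (w_j / rho_j): each component's specific
    volume share. Output is normalized exactly.
    """
    w, rho = _check_weights_densities(weights, densities)
    specific = w / rho
    v = specific / specific.sum()
    if material_ids is None:
        material_ids = [f"component_{i}" for i in range(len(w))]
    if len(material_ids) != len(w):
        raise CompositionError("material_ids length does not match weights")
    return Composition(
        components=tuple(zip(material_ids, v.tolist())),
        weight_fractions=tuple(w.tolist()),
        true_densities=tuple(rho.tolist()),
    )


def mixture_true_density(weights: Sequence[float], densities: Sequence[float]) -> float:
    """True density of a physical mixture from component weight fractions.

    Specific volumes are additive, so rho_mix = 1 / sum_i (w_i / rho_i)
    (the weight-harmonic mean of the component densities).
    """
    w, rho = _check_weights_densities(weights, densities)
    return float(1.0 / np.sum(w / rho))


def _compositions_of(n: int, m: int):
    """Yield all count vectors (k_1..k_m) of non-negative ints summing to n.

    Stars-and-bars enumeration: C(n+m-1, m-1) vectors.
    """
    for bars in combinations(range(n + m - 1), m - 1):
        prev = -1
        counts = []
        for b in bars:
            counts.append(b - prev - 1)
            prev = b
        counts.append(n + m - 2 - prev)
        yield tuple(counts)


def _log_multinomial(n: int, counts: Sequence[int]) -> float:
    """ln of the multinomial coefficient n! / prod(k_j!).

    Exact integer arithmetic up to n = 20, log-gamma beyond (needed for the
    large-order asymptote toward the power law).
    """
    if n <= 20:
        coeff = math.factorial(n)
        for k in counts:
            coeff //= math.factorial(k)
        return math.log(coeff)
    return float(gammaln(n + 1) - sum(gammaln(k + 1) for k in counts))


def cluster_distribution(
    n: int,
    comp: Composition,
    strengths: Sequence[float],
) -> ClusterDistribution:
    """Enumerate all order-n cluster types with probabilities and strengths.

    The probability of a cluster with counts k is the multinomial
    n!/prod(k_j!) * prod(V_j^k_j); its strength is the geometric mean
    prod(sigma_j^(k_j/n)). Both are computed in log space. A cluster that
    contains any particle of a zero-strength component has strength 0 (the
    continuous limit as sigma -> 0).
    """
    if int(n) != n or n < 1:
        raise CompositionError(f"interaction order must be an integer >= 1, got {n!r}")
    n = int(n)
    sigma = np.asarray(strengths, dtype=float)
    if sigma.shape != (len(comp),):
        raise CompositionError(
            f"need one strength per component ({len(comp)}), got shape {sigma.shape}"
        )
    if np.any(sigma < 0):
        raise CompositionError("component strengths must be >= 0")

    v = comp.volume_fractions
    with np.errstate(divide="ignore"):
        log_v = np.log(v)
        log_sigma = np.log(sigma)

    entries = []
    for counts in _compositions_of(n, len(comp)):
        k = np.array(counts, dtype=float)
        active = k > 0
        if np.any(v[active] == 0.0):
            prob = 0.0
        else:
            prob = math.exp(_log_multinomial(n, counts) + float(k[active] @ log_v[active]))
        if np.any(sigma[active] == 0.0):
            strength = 0.0
        else:
            strength = math.exp(float(k[active] @ log_sigma[active]) / n)
        entries.append((ClusterType(counts), prob, strength))
    return ClusterDistribution(order=n, entries=tuple(entries))


def interaction_predict(n: int, comp: Composition, strengths: Sequence[float]) -> float:
    """Mixture tensile strength under the order-n interaction model, in MPa.

    The probability-weighted expectation of cluster strength over the
    order-n cluster distribution.
    """
    return cluster_distribution(n, comp, strengths).expected_strength()


def _check_strengths(comp: Composition, strengths) -> np.ndarray:
    sigma = np.asarray(strengths, dtype=float)
    if sigma.shape != (len(comp),):
        raise CompositionError(
            f"need one strength per component ({len(comp)}), got shape {sigma.shape}"
        )
    if np.any(sigma < 0):
        raise CompositionError("component strengths must be >= 0")
    return sigma


def linear_rule(comp: Composition, strengths: Sequence[float]) -> float:
    """Linear (arithmetic) mixing rule: sigma_mix = sum V_i sigma_i.

    Algebraically identical to the pairwise (order-2) model with
    arithmetic-mean adhesive contact strength.
    """
    sigma = _check_strengths(comp, strengths)
    return float(comp.volume_fractions @ sigma)


def power_law(comp: Composition, strengths: Sequence[float]) -> float:
    """Power law (geometric mixing rule): sigma_mix = prod sigma_i^V_i.

    Models the strength as if every interaction were adhesive; the
    infinite-order limit of the interaction model. Returns 0 when any
    component present (V_i > 0) has zero strength.
    """
    sigma = _check_strengths(comp, strengths)
    v = comp.volume_fractions
    active = v > 0
    if np.any(sigma[active] == 0.0):
        return 0.0
    return float(math.exp(float(v[active] @ np.log(sigma[active]))))


def rd_combination_predict(
    profiles: Sequence[CompactibilityProfile],
    comp: Composition,
    variant: str,
    porosity: float,
) -> float:
    """Classical RD-combination rules: mix R-D parameters, then evaluate.

    The mixture's sigma0 and k are formed from the component profiles'
    parameters by the linear rule (L, volume-weighted arithmetic mean) or
    the power law (P, volume-weighted geometric mean); the two-letter
    variant names the rule for sigma0 then the rule for k. The mixture
    strength is sigma0_mix * exp(-k_mix * eps).
    """
    if variant not in RD_VARIANTS:
        raise ConfigurationError(
            f"unknown RD-combination variant {variant!r}; expected one of {RD_VARIANTS}"
        )
    if len(profiles) != len(comp):
        raise ConfigurationError(
            f"need one profile per component ({len(comp)}), got {len(profiles)}"
        )
    if not 0.0 <= porosity < 1.0:
        raise ConfigurationError(f"porosity must lie in [0, 1), got {porosity!r}")
    sigma0s = np.array([p.sigma0 for p in profiles], dtype=float)
    ks = np.array([p.k for p in profiles], dtype=float)
    v = comp.volume_fractions

    def _mix(values, rule):
        if rule == "L":
            return float(v @ values)
        return float(math.exp(float(v @ np.log(values))))

    sigma0_mix = _mix(sigma0s, variant[0])
    k_mix = _mix(ks, variant[1])
    return sigma0_mix * math.exp(-k_mix * porosity)


def _parse_model_id(model_id: str, order: int | None):
    """Split a model id like 'interaction-4', 'linear', 'rd-PP'."""
    if model_id.startswith("interaction"):
        tail = model_id[len("interaction"):].lstrip("-:")
        if tail:
            order = int(tail)
        elif order is None:
            order = DEFAULT_ORDER
        return "interaction", order
    if model_id in ("linear", "power"):
        return model_id, None
    if model_id.startswith("rd-"):
        variant = model_id[3:].upper()
        if variant not in RD_VARIANTS:
            raise ConfigurationError(f"unknown RD variant in model id {model_id!r}")
        return "rd", variant
    raise ConfigurationError(f"unknown model id {model_id!r}")


def predict_mixture_profile(
    profiles: Sequence[CompactibilityProfile],
    comp: Composition,
    model_id: str,
    porosity_grid: Sequence[float],
    order: int | None = None,
) -> MixturePrediction:
    """Predict a mixture compactibility profile on a porosity grid.

    The core contract is porosity matching: at every grid porosity each
    pure component's strength sigma_i is evaluated from its own R-D profile
    at that SAME porosity, and the chosen mixing model combines those
    matched strengths. Supported model ids: ``interaction`` or
    ``interaction-N`` (N the cluster order, default 4), ``linear``,
    ``power``, and ``rd-LL``/``rd-LP``/``rd-PL``/``rd-PP``.
    """
    by_id = {p.material_id: p for p in profiles}
    missing = [mid for mid in comp.material_ids if mid not in by_id]
    if missing:
        raise ConfigurationError(f"no compactibility profile for material(s): {missing}")
    ordered = [by_id[mid] for mid in comp.material_ids]

    kind, param = _parse_model_id(model_id, order)
    grid = [float(e) for e in porosity_grid]
    strengths_out = []
    for eps in grid:
        if kind == "rd":
            s_mix = rd_combination_predict(ordered, comp, param, eps)
        else:
            sigma = [predict_rd(p, eps) for p in ordered]
            if kind == "interaction":
                s_mix = interaction_predict(param, comp, sigma)
            elif kind == "linear":
                s_mix = linear_rule(comp, sigma)
            else:
                s_mix = power_law(comp, sigma)
        strengths_out.append(s_mix)

    label = f"interaction-{param}" if kind == "interaction" else model_id
    return MixturePrediction(
        model_id=label,
        porosities=tuple(grid),
        strengths=tuple(strengths_out),
    )
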