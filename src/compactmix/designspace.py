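"""Formulation design-space exploration.

Sweeps composition x porosity, predicts mixture tensile strength under a
chosen mixing model, and masks the cells whose predicted strength falls
inside a target window — the composition space that meets the tensile
strength criteria, computed from nothing but the pure-component
compactibility profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .compactibility import CompactibilityProfile
from .exceptions import ConfigurationError
from .mixture_models import Composition, predict_mixture_profile

__all__ = ["DesignSpaceMap", "simplex_grid", "design_space"]


@dataclass(frozen=True)
class DesignSpaceMap:
    """Predicted strengths and acceptance mask over a composition x porosity grid.

    ``strengths[i, j]`` is the predicted sigma_mix (MPa) for
    ``compositions[i]`` at ``porosities[j]``; ``mask[i, j]`` is True iff
    sigma_low <= strengths[i, j] <= sigma_high.
    """

    compositions: tuple[Composition, ...]
    porosities: tuple[float, ...]
    strengths: np.ndarray
    mask: np.ndarray
    target_window: tuple[float, float]
    model_id: str

    def acceptable_compositions(self, porosity_index: int) -> list[Composition]:
        """Compositions meeting the target window at one porosity."""
        return [
            c for c, ok in zip(self.compositions, self.mask[:, porosity_index]) if ok
        ]


def simplex_grid(material_ids: Sequence[str], step: float) -> list[Composition]:
    """All compositions of the given components on a simplex lattice.

    Volume fractions are multiples of ``step`` summing to 1; for two
    components this is the V_A axis from 0 to 1.
    """
    if step <= 0 or step > 1:
        raise ConfigurationError(f"grid step must be in (0, 1], got {step!r}")
    m = len(material_ids)
    if m < 1:
        raise ConfigurationError("need at least one component")
    n_steps = round(1.0 / step)
    if abs(n_steps * step - 1.0) > 1e-9:
        raise ConfigurationError(f"grid step {step!r} does not divide 1 evenly")

    grids: list[Composition] = []

    def _recurse(prefix: list[int], remaining: int):
        if len(prefix) == m - 1:
            counts = prefix + [remaining]
            fracs = [c / n_steps for c in counts]
            grids.append(Composition(components=tuple(zip(material_ids, fracs))))
            return
        for c in range(remaining + 1):
            _recurse(prefix + [c], remaining - c)

    _recurse([], n_steps)
    return grids


def design_space(
    profiles: Sequence[CompactibilityProfile],
    material_ids: Sequence[str],
    composition_step: float,
    porosity_grid: Sequence[float],
    target_window: tuple[float, float],
    model_id: str = "interaction-4",
) -> DesignSpaceMap:
    """Map the acceptable formulation region for a target strength window.

    For binary systems at fixed porosity the acceptable region is a
    contiguous interval in V_A because the interaction model is monotone in
    the volume fraction of the stronger component.
    """
    lo, hi = target_window
    if not lo < hi:
        raise ConfigurationError(
            f"target window must satisfy low < high, got ({lo!r}, {hi!r})"
        )
    grid = [float(e) for e in porosity_grid]
    if not grid:
        raise ConfigurationError("porosity grid is empty")
    comps = simplex_grid(material_ids, composition_step)

    strengths = np.empty((len(comps), len(grid)), dtype=float)
    for i, comp in enumerate(comps):
        pred = predict_mixture_profile(profiles, comp, model_id, grid)
        strengths[i, :] = pred.strengths
    mask = (strengths >= lo) & (strengths <= hi)
    return DesignSpaceMap(
        compositions=tuple(comps),
        porosities=tuple(grid),
        strengths=strengths,
        mask=mask,
        target_window=(float(lo), float(hi)),
        model_id=model_id,
    )
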