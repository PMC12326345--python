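"""Prediction-accuracy evaluation: per-mixture and pooled RMSE, model ranking.

Measured mixture tablets are compared against each candidate model's
prediction at the tablet's own porosity (no binning). The per-mixture RMSE
is sqrt(mean squared residual) over that mixture's tablets; the global
RMSE for a model pools the residuals of all mixtures, so that

    global_rmse^2 = sum_m n_m * rmse_m^2 / sum_m n_m

holds exactly. Models are ranked by global RMSE, ties broken toward the
simpler model (lower interaction order first, classical single-formula
rules before higher-order cluster models).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .compactibility import CompactibilityProfile
from .exceptions import ConfigurationError, EvaluationError
from .mixture_models import Composition, _parse_model_id, predict_mixture_profile

__all__ = [
    "MeasuredMixture",
    "EvaluationResult",
    "ComparisonReport",
    "rmse",
    "evaluate_models",
]


@dataclass(frozen=True)
class MeasuredMixture:
    """Measured (porosity, tensile strength) data for one mixture."""

    mixture_id: str
    composition: Composition
    porosities: tuple[float, ...]
    strengths: tuple[float, ...]

    def __post_init__(self):
        if len(self.porosities) != len(self.strengths):
            raise EvaluationError("porosities and strengths differ in length")
        if len(self.porosities) == 0:
            raise EvaluationError("a measured mixture needs at least one point")


@dataclass(frozen=True)
class EvaluationResult:
    """Measured-vs-predicted pairs and RMSE for one mixture under one model."""

    mixture_id: str
    model_id: str
    pairs: tuple[tuple[float, float, float], ...]  # (porosity, measured, predicted)
    rmse: float

    @property
    def n_points(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ComparisonReport:
    """Multi-model comparison over a shared measured dataset.

    ``per_mixture`` maps model_id -> tuple of per-mixture EvaluationResults;
    ``global_rmse`` maps model_id -> RMSE over the pooled residuals;
    ``ranking`` lists model_ids from best (lowest global RMSE) to worst.
    """

    per_mixture: Mapping[str, tuple[EvaluationResult, ...]]
    global_rmse: Mapping[str, float]
    ranking: tuple[str, ...]

    def best_model(self) -> str:
        return self.ranking[0]


def rmse(measured: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-square error between measured and predicted strengths.

    RMSE = sqrt( sum_i (sigma_measured_i - sigma_predicted_i)^2 / n ).
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1:
        raise EvaluationError(
            f"measured and predicted must be equal-length 1-D, got {m.shape} vs {p.shape}"
        )
    if m.size == 0:
        raise EvaluationError("cannot compute RMSE of empty vectors")
    return float(np.sqrt(np.mean((m - p) ** 2)))


def _simplicity_key(model_id: str) -> tuple[int, int]:
    """Tie-break ordering: classical one-formula rules, then cluster orders."""
    kind, param = _parse_model_id(model_id, None)
    if kind in ("linear", "power"):
        return (0, 0)
    if kind == "rd":
        return (1, 0)
    return (2, param)


def evaluate_models(
    mixtures: Sequence[MeasuredMixture],
    profiles: Sequence[CompactibilityProfile],
    model_ids: Sequence[str],
) -> ComparisonReport:
    """Evaluate every model on every measured mixture and rank by global RMSE.

    For each mixture x model, predictions are computed at the measured
    tablets' actual porosities via :func:`predict_mixture_profile`; the
    global RMSE per model pools residuals over all mixtures. A missing
    component profile raises :class:`ConfigurationError` naming the
    material.
    """
    if not mixtures:
        raise EvaluationError("no measured mixtures supplied")
    if not model_ids:
        raise EvaluationError("no models supplied")
    available = {p.material_id for p in profiles}
    missing = sorted(
        {mid for mx in mixtures for mid in mx.composition.material_ids} - available
    )
    if missing:
        raise ConfigurationError(f"no compactibility profile for material(s): {missing}")

    per_mixture: dict[str, tuple[EvaluationResult, ...]] = {}
    global_rmse: dict[str, float] = {}
    for model_id in model_ids:
        results = []
        pooled_sq = 0.0
        pooled_n = 0
        label = None
        for mx in mixtures:
            pred = predict_mixture_profile(
                profiles, mx.composition, model_id, mx.porosities
            )
            label = pred.model_id
            pairs = tuple(zip(mx.porosities, mx.strengths, pred.strengths))
            r = rmse(mx.strengths, pred.strengths)
            results.append(
                EvaluationResult(
                    mixture_id=mx.mixture_id, model_id=label, pairs=pairs, rmse=r
                )
            )
            pooled_sq += r**2 * len(pairs)
            pooled_n += len(pairs)
        per_mixture[label] = tuple(results)
        global_rmse[label] = float(np.sqrt(pooled_sq / pooled_n))

    ranking = tuple(
        sorted(global_rmse, key=lambda mid: (global_rmse[mid], _simplicity_key(mid), mid))
    )
    return ComparisonReport(
        per_mixture=per_mixture, global_rmse=global_rmse, ranking=ranking
    )
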