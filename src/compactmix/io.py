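"""Delimited-text readers and writers for the package's table formats.

Fixed dialect to keep outputs diff-stable: comma separation, dot decimal,
UTF-8, mandatory header row. Compositions in mixture tables are encoded in
a single column as ``material=volfrac;material=volfrac``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .compactibility import CompactibilityProfile, CompactPoint, TabletMeasurement
from .evaluation import ComparisonReport, MeasuredMixture
from .exceptions import CompactMixError
from .mixture_models import ClusterDistribution, Composition, MixturePrediction

TABLET_COLUMNS = [
    "material", "weight_g", "diameter_mm", "thickness_mm", "force_N",
    "true_density_g_cm3",
]
POINT_COLUMNS = ["material", "porosity", "tensile_strength_MPa"]
PROFILE_COLUMNS = [
    "material", "sigma0_MPa", "k", "eps_min", "eps_max", "n_points", "rss",
]
MIXTURE_COLUMNS = ["mixture_id", "composition", "porosity", "sigma_MPa"]


class TableFormatError(CompactMixError, ValueError):
    """A delimited table is missing required columns or is malformed."""


def _fmt_float(x) -> str:
    """Shortest representation that round-trips the float64 exactly."""
    return repr(float(x))


def _read(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_tablet_table(path) -> dict[str, list[TabletMeasurement]]:
    """Read a raw tablet measurement table, grouped by material."""
    df = _read(path, TABLET_COLUMNS)
    out: dict[str, list[TabletMeasurement]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.material), []).append(
            TabletMeasurement(
                weight=float(row.weight_g),
                diameter=float(row.diameter_mm),
                thickness=float(row.thickness_mm),
                failure_force=float(row.force_N),
                true_density=float(row.true_density_g_cm3),
            )
        )
    return out


def write_tablet_table(path, tablets: dict[str, list[TabletMeasurement]]) -> None:
    rows = [
        {
            "material": mid,
            "weight_g": t.weight,
            "diameter_mm": t.diameter,
            "thickness_mm": t.thickness,
            "force_N": t.failure_force,
            "true_density_g_cm3": t.true_density,
        }
        for mid, ts in tablets.items()
        for t in ts
    ]
    pd.DataFrame(rows, columns=TABLET_COLUMNS).to_csv(path, index=False, float_format=_fmt_float)


def read_point_table(path) -> dict[str, list[CompactPoint]]:
    """Read a (porosity, tensile strength) point table, grouped by material."""
    df = _read(path, POINT_COLUMNS)
    out: dict[str, list[CompactPoint]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.material), []).append(
            CompactPoint(float(row.porosity), float(row.tensile_strength_MPa))
        )
    return out


def write_point_table(path, points: dict[str, list[CompactPoint]]) -> None:
    rows = [
        {"material": mid, "porosity": p.porosity,
         "tensile_strength_MPa": p.tensile_strength}
        for mid, ps in points.items()
        for p in ps
    ]
    pd.DataFrame(rows, columns=POINT_COLUMNS).to_csv(path, index=False, float_format=_fmt_float)


def read_profile_table(path) -> list[CompactibilityProfile]:
    df = _read(path, PROFILE_COLUMNS[:3])
    profiles = []
    for row in df.itertuples(index=False):
        rng = None
        if "eps_min" in df.columns and "eps_max" in df.columns:
            if pd.notna(row.eps_min) and pd.notna(row.eps_max):
                rng = (float(row.eps_min), float(row.eps_max))
        profiles.append(
            CompactibilityProfile(
                material_id=str(row.material),
                sigma0=float(row.sigma0_MPa),
                k=float(row.k),
                fitted_porosity_range=rng,
                n_points=int(row.n_points)
                if "n_points" in df.columns and pd.notna(row.n_points) else None,
                rss=float(row.rss)
                if "rss" in df.columns and pd.notna(row.rss) else None,
            )
        )
    return profiles


def write_profile_table(path, profiles: Sequence[CompactibilityProfile]) -> None:
    rows = []
    for p in profiles:
        rng = p.fitted_porosity_range
        rows.append(
            {
                "material": p.material_id,
                "sigma0_MPa": p.sigma0,
                "k": p.k,
                "eps_min": rng[0] if rng else None,
                "eps_max": rng[1] if rng else None,
                "n_points": p.n_points,
                "rss": p.rss,
            }
        )
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False, float_format=_fmt_float)


def format_composition(comp: Composition) -> str:
    return ";".join(f"{mid}={v:.10g}" for mid, v in comp.components)


def parse_composition(spec: str) -> Composition:
    """Parse ``material=volfrac;material=volfrac`` into a Composition."""
    parts = [p for p in spec.split(";") if p.strip()]
    comps = []
    for part in parts:
        if "=" not in part:
            raise TableFormatError(
                f"bad composition token {part!r}; expected material=fraction"
            )
        mid, _, val = part.partition("=")
        comps.append((mid.strip(), float(val)))
    return Composition(components=tuple(comps))


def read_mixture_table(path) -> list[MeasuredMixture]:
    """Read a measured-mixture table into MeasuredMixture records."""
    df = _read(path, MIXTURE_COLUMNS)
    mixtures = []
    for mixture_id, group in df.groupby("mixture_id", sort=False):
        comp_strs = group["composition"].unique()
        if len(comp_strs) != 1:
            raise TableFormatError(
                f"mixture {mixture_id!r} has inconsistent composition strings"
            )
        mixtures.append(
            MeasuredMixture(
                mixture_id=str(mixture_id),
                composition=parse_composition(comp_strs[0]),
                porosities=tuple(float(e) for e in group["porosity"]),
                strengths=tuple(float(s) for s in group["sigma_MPa"]),
            )
        )
    return mixtures


def write_mixture_table(path, mixtures: Sequence[MeasuredMixture]) -> None:
    rows = [
        {
            "mixture_id": mx.mixture_id,
            "composition": format_composition(mx.composition),
            "porosity": e,
            "sigma_MPa": s,
        }
        for mx in mixtures
        for e, s in zip(mx.porosities, mx.strengths)
    ]
    pd.DataFrame(rows, columns=MIXTURE_COLUMNS).to_csv(path, index=False, float_format=_fmt_float)


def prediction_frame(pred: MixturePrediction) -> pd.DataFrame:
    order = None
    if pred.model_id.startswith("interaction-"):
        order = int(pred.model_id.split("-")[1])
    return pd.DataFrame(
        {
            "porosity": pred.porosities,
            "sigma_pred_MPa": pred.strengths,
            "model": pred.model_id,
            "order": order,
        }
    )


def cluster_frame(dist: ClusterDistribution, material_ids: Sequence[str]) -> pd.DataFrame:
    rows = []
    for ct, prob, strength in dist.entries:
        row = {f"n_{mid}": k for mid, k in zip(material_ids, ct.counts)}
        row.update(
            order=dist.order, probability=prob, cluster_strength_MPa=strength,
            cohesive=ct.is_cohesive,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def comparison_frames(report: ComparisonReport) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-mixture RMSE table, global RMSE/ranking table)."""
    per_rows = [
        {
            "model": model_id,
            "mixture_id": res.mixture_id,
            "n_points": res.n_points,
            "rmse_MPa": res.rmse,
        }
        for model_id, results in report.per_mixture.items()
        for res in results
    ]
    global_rows = [
        {"rank": i + 1, "model": mid, "global_rmse_MPa": report.global_rmse[mid]}
        for i, mid in enumerate(report.ranking)
    ]
    return pd.DataFrame(per_rows), pd.DataFrame(global_rows)
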