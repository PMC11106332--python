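"""Nomogram point-scale construction and export.

Converts an unpenalized Cox fit into the classical point scale: the
feature with the largest |beta| x (feature range) spans exactly 0-100
points, every other feature is scaled proportionally, and the total-points
axis maps to predicted survival probabilities at each requested horizon
through the model's baseline survival.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import CoxFit, predict_survival

__all__ = ["NomogramSpec", "build_nomogram", "total_points",
           "survival_from_points", "export_nomogram", "load_nomogram"]


@dataclass
class NomogramSpec:
    """Tabulated nomogram: per-feature point anchors, the total-points
    range, and per-horizon total-points -> survival grids."""

    feature_points: dict[str, list[tuple[float, float]]]  # value -> points
    total_points_range: tuple[float, float]
    survival_maps: dict[float, list[tuple[float, float]]]  # per horizon
    model_family: str
    outcome: str
    horizons: tuple
    scale: float  # points per unit of linear predictor
    lp_offset: float  # lp at the zero-point corner
    age_anchor_range: tuple | None = None
    meta: dict = field(default_factory=dict)


def build_nomogram(fit: CoxFit, horizons, outcome: str = "os",
                   age_anchor_range: tuple[float, float] | None = None,
                   grid_points: int = 500) -> NomogramSpec:
    """Lay out the point scales for an unpenalized Cox fit.

    points(feature, value) = 100 * beta_f * (value - min_f) / max_g(|beta_g| * range_g)
    with binary dummies ranging over {0, 1} and numeric age over
    ``age_anchor_range``.  Negative-effect features anchor their points at
    the high end so all point values stay >= 0.
    """
    if fit.hr_ci_p is None:
        raise ValueError(
            "penalized fits carry no identifiable basis for a nomogram; "
            "refit the selected features (cox_with_lasso) first"
        )
    ranges: dict[str, tuple[float, float]] = {}
    for f in fit.feature_names:
        if f == "age_years":
            if age_anchor_range is None:
                raise ValueError("age is in the model; provide age_anchor_range")
            ranges[f] = (float(age_anchor_range[0]), float(age_anchor_range[1]))
        else:
            ranges[f] = (0.0, 1.0)

    spans = {f: abs(b) * (ranges[f][1] - ranges[f][0])
             for f, b in zip(fit.feature_names, fit.beta)}
    max_span = max(spans.values())
    if max_span <= 0:
        raise ValueError("all model effects are zero; no point scale exists")
    scale = 100.0 / max_span  # points per unit |beta * value|

    feature_points: dict[str, list[tuple[float, float]]] = {}
    lp_offset = 0.0  # linear predictor of the all-zero-points patient
    for f, b in zip(fit.feature_names, fit.beta):
        lo, hi = ranges[f]
        # anchor at the value minimizing beta*value so points >= 0
        anchor = lo if b >= 0 else hi
        lp_offset += b * anchor
        if f == "age_years":
            vals = np.linspace(lo, hi, 16)
        else:
            vals = np.array([0.0, 1.0])
        pts = scale * (b * vals - b * anchor)
        feature_points[f] = [(float(v), float(p)) for v, p in zip(vals, pts)]

    total_max = float(sum(max(p for _, p in pts) for pts in feature_points.values()))
    survival_maps: dict[float, list[tuple[float, float]]] = {}
    grid = np.linspace(0.0, total_max, grid_points)
    for h in horizons:
        lp = lp_offset + grid / scale
        idx = np.searchsorted(fit.baseline_times, float(h), side="right") - 1
        h0 = fit.baseline_cumhaz[idx] if idx >= 0 else 0.0
        if float(h) > fit.baseline_times[-1]:
            warnings.warn(f"horizon {h} beyond baseline grid; using last point")
        s = np.exp(-h0) ** np.exp(lp)
        survival_maps[float(h)] = [(float(g), float(v)) for g, v in zip(grid, s)]

    return NomogramSpec(
        feature_points=feature_points,
        total_points_range=(0.0, total_max),
        survival_maps=survival_maps,
        model_family=fit.family,
        outcome=outcome,
        horizons=tuple(float(h) for h in horizons),
        scale=scale,
        lp_offset=float(lp_offset),
        age_anchor_range=tuple(age_anchor_range) if age_anchor_range else None,
    )


def total_points(spec: NomogramSpec, rows: pd.DataFrame) -> np.ndarray:
    """Sum of per-feature points for encoded patient rows (linear
    interpolation on numeric scales)."""
    tot = np.zeros(len(rows))
    for f, pts in spec.feature_points.items():
        vals = np.array([v for v, _ in pts])
        ps = np.array([p for _, p in pts])
        x = rows[f].to_numpy(dtype=float)
        tot += np.interp(x, vals, ps)
    return tot


def survival_from_points(spec: NomogramSpec, points: np.ndarray,
                         horizon: float) -> np.ndarray:
    """Read predicted survival off the tabulated total-points axis."""
    tab = spec.survival_maps[float(horizon)]
    g = np.array([a for a, _ in tab])
    s = np.array([b for _, b in tab])
    return np.interp(points, g, s)


def export_nomogram(spec: NomogramSpec, path) -> None:
    payload = {
        "feature_points": {k: v for k, v in spec.feature_points.items()},
        "total_points_range": list(spec.total_points_range),
        "survival_maps": {str(k): v for k, v in spec.survival_maps.items()},
        "model_family": spec.model_family,
        "outcome": spec.outcome,
        "horizons": list(spec.horizons),
        "scale": spec.scale,
        "lp_offset": spec.lp_offset,
        "age_anchor_range": list(spec.age_anchor_range)
        if spec.age_anchor_range else None,
        "meta": spec.meta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_nomogram(path) -> NomogramSpec:
    with open(path) as fh:
        raw = json.load(fh)
    return NomogramSpec(
        feature_points={k: [tuple(x) for x in v]
                        for k, v in raw["feature_points"].items()},
        total_points_range=tuple(raw["total_points_range"]),
        survival_maps={float(k): [tuple(x) for x in v]
                       for k, v in raw["survival_maps"].items()},
        model_family=raw["model_family"],
        outcome=raw["outcome"],
        horizons=tuple(raw["horizons"]),
        scale=raw["scale"],
        lp_offset=raw["lp_offset"],
        age_anchor_range=tuple(raw["age_anchor_range"])
        if raw["age_anchor_range"] else None,
        meta=raw.get("meta", {}),
    )
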