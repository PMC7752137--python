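"""Perimeter-based G-ratio morphometry from paired fiber contours.

For each myelinated fiber annotated with a closed axon-boundary polygon
inside a closed myelin outer-boundary polygon, the G-ratio is the ratio of
the two polygon perimeters,

    g = P_axon / P_myelin,          0 < g < 1,

with lower values indicating thicker myelin relative to the axon. Axon
diameter and myelin thickness use perimeter-equivalent-circle conventions by
default (d = P/pi, thickness = (P_myelin - P_axon) / 2 pi), consistent with
the perimeter-based g; area-equivalent variants are available by flag since
field usage varies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .errors import ValidationError
from .io import FiberContourPair, FiberContourTable
from .morphometry import GroupComparison, compare_groups

__all__ = ["FiberMetrics", "polygon_perimeter", "fiber_metrics",
           "summarize_fibers", "GroupSummary", "gratio_by_diameter_bins"]


@dataclass
class FiberMetrics:
    fiber_id: str
    p_axon: float
    p_myelin: float
    g_ratio: float
    axon_diameter: float
    myelin_thickness: float
    unit: str = "nm"
    diameter_mode: str = "perimeter"


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float


def polygon_perimeter(contour, validate: bool = True) -> float:
    """Sum of consecutive edge lengths of a closed polygon (closure implicit).

    Orientation-invariant; with ``validate`` the polygon must be simple.
    """
    verts = np.asarray(contour, float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValidationError("polygon needs >= 3 (x, y) vertices")
    if validate and not Polygon(verts).is_valid:
        raise ValidationError("polygon is self-intersecting")
    diffs = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    return float(np.sum(np.hypot(diffs[:, 0], diffs[:, 1])))


def fiber_metrics(pair: FiberContourPair, unit: str = "nm",
                  diameter_mode: str = "perimeter") -> FiberMetrics:
    """G-ratio, axon diameter and myelin thickness for one fiber.

    ``diameter_mode="perimeter"`` uses perimeter-equivalent circles;
    ``"area"`` uses area-equivalent circles (d = 2 sqrt(A/pi), thickness =
    R_area(myelin) - R_area(axon)). The g-ratio itself is always the
    perimeter ratio.
    """
    if diameter_mode not in ("perimeter", "area"):
        raise ValidationError("diameter_mode must be 'perimeter' or 'area'")
    p_axon = polygon_perimeter(pair.axon, validate=False)  # validated at construction
    p_myelin = polygon_perimeter(pair.myelin, validate=False)
    if p_axon >= p_myelin:
        raise ValidationError(
            f"fiber {pair.fiber_id}: axon perimeter {p_axon:.6g} >= myelin "
            f"perimeter {p_myelin:.6g} (g-ratio must be < 1)")
    g = p_axon / p_myelin
    if diameter_mode == "perimeter":
        diameter = p_axon / math.pi
        thickness = (p_myelin - p_axon) / (2.0 * math.pi)
    else:
        a_axon = Polygon(pair.axon).area
        a_myelin = Polygon(pair.myelin).area
        r_axon = math.sqrt(a_axon / math.pi)
        r_myelin = math.sqrt(a_myelin / math.pi)
        diameter = 2.0 * r_axon
        thickness = r_myelin - r_axon
    return FiberMetrics(pair.fiber_id, p_axon, p_myelin, g, diameter,
                        thickness, unit=unit, diameter_mode=diameter_mode)


def compute_table_metrics(table: FiberContourTable,
                          diameter_mode: str = "perimeter") -> list[FiberMetrics]:
    return [fiber_metrics(p, unit=table.unit, diameter_mode=diameter_mode)
            for p in table.fibers]


def summarize_fibers(metrics: list[FiberMetrics],
                     labels: list[str] | dict[str, str]
                     ) -> tuple[dict[str, GroupSummary], GroupComparison | None]:
    """Per-group mean/SD/n of the g-ratio plus a two-group t-test.

    ``labels`` is a per-fiber list aligned with ``metrics`` or a mapping
    fiber_id -> group. The comparison is returned only for exactly two
    groups.
    """
    if isinstance(labels, dict):
        labels = [labels[m.fiber_id] for m in metrics]
    if len(labels) != len(metrics):
        raise ValidationError("need one group label per fiber")
    by_group: dict[str, list[float]] = {}
    for m, lab in zip(metrics, labels):
        by_group.setdefault(str(lab), []).append(m.g_ratio)
    for lab, vals in by_group.items():
        if len(vals) < 2:
            raise ValidationError(f"group {lab!r} needs >= 2 fibers")
    summaries = {
        lab: GroupSummary(lab, len(v), float(np.mean(v)), float(np.std(v, ddof=1)))
        for lab, v in by_group.items()
    }
    comparison = None
    if len(by_group) == 2:
        (la, va), (lb, vb) = sorted(by_group.items())
        comparison = compare_groups(va, vb)
    return summaries, comparison


def gratio_by_diameter_bins(metrics: list[FiberMetrics], n_bins: int = 4
                            ) -> list[dict]:
    """Optional g-ratio report binned by axon-diameter quantile, guarding
    against diameter differences confounding group comparisons."""
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    d = np.array([m.axon_diameter for m in metrics])
    g = np.array([m.g_ratio for m in metrics])
    edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
    out = []
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        sel = (d >= lo) & (d <= hi if i == n_bins - 1 else d < hi)
        out.append({"bin": i, "d_low": float(lo), "d_high": float(hi),
                    "n": int(sel.sum()),
                    "g_mean": float(g[sel].mean()) if sel.any() else float("nan")})
    return out
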