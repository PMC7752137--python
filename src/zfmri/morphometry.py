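"""Skull-normalized brain morphometry and two-group statistics.

Brain size is summarized by landmark-pair distances — brain length
(olfactory-bulb tip to tectum end), maximum tectum width, maximum brain
height — each divided by the same specimen's skull width so that smaller
animals are compared on shape, not size. Groups are compared with a
two-sample two-tailed t-test (pooled-variance Student by default, Welch by
flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, ValidationError
from .io import LandmarkSet

__all__ = ["MorphoMeasure", "GroupComparison", "measure_distance",
           "normalize_to_skull", "measure_brain", "compare_groups",
           "MEASUREMENT_ENDPOINTS"]

# landmark names delimiting each measurement (manual annotation convention)
MEASUREMENT_ENDPOINTS = {
    "brain_length": ("olfactory_tip", "tectum_end"),
    "tectum_width": ("tectum_left", "tectum_right"),
    "brain_height": ("brain_top", "brain_bottom"),
    "skull_width": ("skull_left", "skull_right"),
}


@dataclass
class MorphoMeasure:
    name: str
    endpoints: tuple[tuple[float, float, float], tuple[float, float, float]]
    value_mm: float
    normalized: float | None = None


@dataclass
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    method: str


def measure_distance(a, b, voxel_size) -> float:
    """Euclidean distance in mm between two voxel-space points.

    Points are (x, y, slice) voxel coordinates (sub-pixel allowed);
    ``voxel_size`` is the per-axis spacing in mm.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    vs = np.asarray(voxel_size, float)
    if a.shape != (3,) or b.shape != (3,) or vs.shape != (3,):
        raise ValidationError("points and voxel_size must be 3-vectors")
    if np.any(vs <= 0):
        raise ValidationError("voxel_size must be positive")
    return float(np.linalg.norm((a - b) * vs))


def normalize_to_skull(measure_mm: float, skull_width_mm: float) -> float:
    """Unitless ratio measurement / same-specimen skull width."""
    if skull_width_mm <= 0:
        raise DomainError("skull_width must be > 0")
    return float(measure_mm) / float(skull_width_mm)


def measure_brain(landmarks: LandmarkSet, voxel_size) -> dict[str, MorphoMeasure]:
    """Compute the four representative measurements from a specimen's
    landmark set and normalize each to the specimen's skull width."""
    values: dict[str, MorphoMeasure] = {}
    for name, (na, nb) in MEASUREMENT_ENDPOINTS.items():
        if na not in landmarks.points or nb not in landmarks.points:
            raise ValidationError(
                f"measurement {name!r} needs landmarks {na!r} and {nb!r}")
        pa, pb = landmarks.points[na], landmarks.points[nb]
        values[name] = MorphoMeasure(name, (pa, pb),
                                     measure_distance(pa, pb, voxel_size))
    skull = values["skull_width"].value_mm
    for m in values.values():
        m.normalized = normalize_to_skull(m.value_mm, skull)
    return values


def compare_groups(a, b, method: str = "student") -> GroupComparison:
    """Two-sample two-tailed t-test between groups ``a`` and ``b``.

    ``method``: ``"student"`` (pooled variance, the default) or ``"welch"``.
    """
    if method not in ("student", "welch"):
        raise ValidationError("method must be 'student' or 'welch'")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("group values must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        raise DomainError("t statistic undefined: zero variance and equal means")
    res = stats.ttest_ind(a, b, equal_var=(method == "student"))
    if method == "student":
        df = a.size + b.size - 2
    else:
        df = float(res.df)
    return GroupComparison(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=int(b.size),
        t_statistic=float(res.statistic), degrees_of_freedom=float(df),
        p_value=float(res.pvalue), method=method)
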