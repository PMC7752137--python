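"""White-matter ROI intensity normalization on T2-weighted images.

Signal in the periventricular grey zone (PGZ; the white-matter-adjacent zone
of the optic tectum) is read as the mean of a small square pixel block
(2 x 2 by default) and divided by the mean of an equal block in the optic
tectum grey matter on the same slice. Measurements are taken on the slice at
the caudal end of the rhombencephalic ventricle and on additional slices
moving rostrally; the per-specimen summary is the mean of the per-slice
ratios (per-slice values are always returned so alternates can be
computed).

The ROI footprint convention is bit-exact: for a sub-pixel ``center`` the
block's upper-left corner is ``round(center - (size - 1) / 2)`` per axis
(numpy banker's rounding), and the block must lie fully inside the slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .io import RoiSpec, Volume

__all__ = ["RoiMeasurement", "extract_roi_mean", "normalized_wm_intensity"]


@dataclass
class RoiMeasurement:
    slice_index: int
    pgz_mean: float
    tectum_mean: float
    normalized: float  # pgz / tectum by default; direction recorded by caller


def extract_roi_mean(slice_image: np.ndarray, center, size: int) -> float:
    """Arithmetic mean of the ``size`` x ``size`` block anchored at ``center``."""
    img = np.asarray(slice_image, float)
    if img.ndim != 2:
        raise ValidationError("slice_image must be 2D")
    if size < 1:
        raise ValidationError("roi size must be >= 1")
    cx, cy = float(center[0]), float(center[1])
    ux = int(np.round(cx - (size - 1) / 2))
    uy = int(np.round(cy - (size - 1) / 2))
    if ux < 0 or uy < 0 or ux + size > img.shape[0] or uy + size > img.shape[1]:
        raise ValidationError(
            f"ROI footprint [{ux}:{ux + size}, {uy}:{uy + size}] outside "
            f"slice of shape {img.shape}")
    return float(img[ux:ux + size, uy:uy + size].mean())


def normalized_wm_intensity(volume: Volume, spec: RoiSpec,
                            flip_ratio: bool = False
                            ) -> tuple[list[RoiMeasurement], float]:
    """Per-slice PGZ/tectum intensity ratios plus their mean.

    ``flip_ratio`` inverts the direction (tectum / PGZ); the default follows
    white-over-grey.
    """
    measurements: list[RoiMeasurement] = []
    nz = volume.shape[2]
    for s in spec.slice_indices():
        if not 0 <= s < nz:
            raise ValidationError(f"ROI slice {s} outside volume with {nz} slices")
        plane = volume.data[:, :, s]
        pgz_c, tect_c = spec.centers[s]
        pgz = extract_roi_mean(plane, pgz_c, spec.roi_size)
        tect = extract_roi_mean(plane, tect_c, spec.roi_size)
        num, den = (tect, pgz) if flip_ratio else (pgz, tect)
        if den == 0:
            raise DomainError(f"slice {s}: reference ROI mean is zero")
        measurements.append(RoiMeasurement(s, pgz, tect, num / den))
    summary = float(np.mean([m.normalized for m in measurements]))
    return measurements, summary
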