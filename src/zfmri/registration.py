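"""Landmark-based in-plane rigid motion correction.

Sub-pixel specimen motion between acquisitions is modelled as a 2D rigid
body transform (rotation + translation, no scaling) estimated from named
landmarks on one representative slice — the two eye-lens centers and the
vagal-lobe tip in the intended use — by closed-form orthogonal Procrustes,
then applied identically to every slice of the volume with bilinear
interpolation (background filled with 0, matching magnitude images).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .io import AcquisitionSeries, LandmarkSet, Volume

__all__ = ["RigidTransform2D", "estimate_rigid2d", "apply_transform_slicewise",
           "align_series", "average_volumes"]


@dataclass
class RigidTransform2D:
    """p -> R(theta) @ (p - center) + center + (tx, ty), acting on (x, y)."""

    theta: float
    tx: float
    ty: float
    center: tuple[float, float] = (0.0, 0.0)
    rms_residual: float = 0.0  # landmark fit residual; metadata, not geometry
    rotation_well_posed: bool = True

    @property
    def rotation(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        c = np.asarray(self.center, float)
        return (pts - c) @ self.rotation.T + c + np.array([self.tx, self.ty])

    def apply_to_landmarks(self, lm: LandmarkSet, frame_id: str | None = None) -> LandmarkSet:
        pts = {}
        for name, (x, y, s) in lm.points.items():
            nx, ny = self.apply([[x, y]])[0]
            pts[name] = (float(nx), float(ny), s)
        return LandmarkSet(frame_id or lm.frame_id, pts)

    def inverse(self) -> "RigidTransform2D":
        # q = R(p - c) + c + t  =>  p = R^T(q - c) + c + (R^T(c - b) - c)
        # with b = c + t - R c the affine offset of the forward map.
        c = np.asarray(self.center, float)
        _, b = self.as_affine()
        tprime = self.rotation.T @ (c - b) - c
        return RigidTransform2D(-self.theta, float(tprime[0]), float(tprime[1]),
                                (float(c[0]), float(c[1])))

    def as_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (A, b) with q = A p + b."""
        c = np.asarray(self.center, float)
        t = np.array([self.tx, self.ty])
        A = self.rotation
        b = c + t - A @ c
        return A, b


def estimate_rigid2d(src: LandmarkSet, dst: LandmarkSet) -> RigidTransform2D:
    """Least-squares rigid transform mapping ``src`` landmarks onto ``dst``.

    Closed-form 2D orthogonal Procrustes: centroid alignment followed by SVD
    of the 2x2 cross-covariance with reflections excluded. With coincident
    source points the rotation is ill-posed: a translation-only transform is
    returned and flagged.
    """
    shared = sorted(src.names() & dst.names())
    if len(shared) < 2:
        raise ValidationError(
            f"need >= 2 shared landmark names, got {len(shared)}: {shared}")
    p = src.xy(shared)
    q = dst.xy(shared)
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    H = p0.T @ q0
    well_posed = np.linalg.norm(H) > 1e-12 * (1.0 + np.linalg.norm(p0))
    if well_posed:
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, d]) @ U.T
        theta = float(np.arctan2(R[1, 0], R[0, 0]))
    else:
        R = np.eye(2)
        theta = 0.0
    t = qc - pc
    tform = RigidTransform2D(theta, float(t[0]), float(t[1]),
                             center=(float(pc[0]), float(pc[1])),
                             rotation_well_posed=bool(well_posed))
    resid = tform.apply(p) - q
    tform.rms_residual = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return tform


def apply_transform_slicewise(vol: Volume, tform: RigidTransform2D) -> Volume:
    """Resample every slice of ``vol`` under ``tform`` (bilinear, 0-filled).

    The output at in-plane position x holds the input at T^{-1}(x), i.e. the
    image content moves by T, as when correcting motion with the transform
    that maps the moving frame's landmarks onto the reference frame's.
    """
    A, b = tform.as_affine()
    # out[x] = in[A_inv x + offset] slice-by-slice; do all slices in one call
    A_inv = np.linalg.inv(A)
    offset2 = -A_inv @ b
    M = np.eye(3)
    M[:2, :2] = A_inv
    offset = np.array([offset2[0], offset2[1], 0.0])
    data = ndimage.affine_transform(vol.data, M, offset=offset, order=1,
                                    mode="constant", cval=0.0, prefilter=False)
    return Volume(data, vol.voxel_size)


def align_series(series: AcquisitionSeries,
                 landmarks: list[LandmarkSet] | dict[str, LandmarkSet],
                 reference_index: int = 0
                 ) -> tuple[AcquisitionSeries, list[RigidTransform2D]]:
    """Map every volume of a series into the reference volume's frame.

    One landmark set per volume is required (ordered list, or dict keyed by
    frame id in series order). One transform is estimated per volume from
    the representative slice's landmarks and applied to all slices;
    repetitions share their time point's transform.
    """
    if isinstance(landmarks, dict):
        landmarks = list(landmarks.values())
    if len(landmarks) != len(series.volumes):
        raise ValidationError(
            f"need one landmark set per volume: {len(landmarks)} sets, "
            f"{len(series.volumes)} volumes")
    if not 0 <= reference_index < len(series.volumes):
        raise ValidationError("reference_index out of range")
    ref = landmarks[reference_index]
    transforms = [estimate_rigid2d(lm, ref) for lm in landmarks]
    vols = [apply_transform_slicewise(v, t) for v, t in zip(series.volumes, transforms)]
    reps = None
    if series.repetitions is not None:
        reps = [[apply_transform_slicewise(r, t) for r in rep_list]
                for rep_list, t in zip(series.repetitions, transforms)]
    out = AcquisitionSeries(vols, series.series_type, series.times_ms.copy(), reps)
    return out, transforms


def average_volumes(vols: list[Volume]) -> Volume:
    """Voxelwise arithmetic mean of equally shaped volumes."""
    if not vols:
        raise ValidationError("cannot average an empty volume list")
    shape, spacing = vols[0].shape, vols[0].voxel_size
    for v in vols:
        if v.shape != shape or v.voxel_size != spacing:
            raise ValidationError("averaging requires equal shapes and spacings")
    return Volume(np.mean([v.data for v in vols], axis=0), spacing)
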