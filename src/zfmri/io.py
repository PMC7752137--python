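"""Readers/writers for volumes, acquisition series, landmarks, ROI specs and
fiber contours.

Conventions
-----------
* Volumes are NIfTI-1 (``.nii``/``.nii.gz``) with a JSON sidecar/manifest
  carrying acquisition metadata (series type, TR or TE list, voxel spacing).
* Array axes are ``(x, y, z)`` with ``x`` = left-right, ``y`` = dorso-ventral
  and ``z`` = the rostro-caudal slice axis; indices are 0-based and landmark
  coordinates may be sub-pixel.
* All tables are UTF-8 tab-separated text with a header row so that fixtures
  diff cleanly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
import shapely
from shapely.geometry import Polygon

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

SERIES_MANIFEST = "series.json"


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3D magnitude image with isotropic-or-not voxel spacing in mm."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(f"volume must be 3D, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class AcquisitionSeries:
    """An ordered set of co-registered volumes indexed by TR (T1) or TE (T2).

    ``repetitions``, when present, holds the raw repeated acquisitions per
    time point; ``volumes`` then carries one representative (typically the
    repetition average) per time point.
    """

    volumes: list[Volume]
    series_type: str  # "T1" or "T2"
    times_ms: np.ndarray
    repetitions: list[list[Volume]] | None = None

    def __post_init__(self) -> None:
        if self.series_type not in ("T1", "T2"):
            raise ValidationError(f"series_type must be 'T1' or 'T2', got {self.series_type!r}")
        self.times_ms = np.asarray(self.times_ms, dtype=np.float64)
        if len(self.volumes) < 2:
            raise ValidationError("a series needs at least 2 time points")
        if len(self.times_ms) != len(self.volumes):
            raise ValidationError("times_ms and volumes must have equal length")
        if np.any(self.times_ms <= 0) or np.any(np.diff(self.times_ms) <= 0):
            raise ValidationError(f"times_ms must be strictly increasing and > 0: {self.times_ms}")
        shape = self.volumes[0].shape
        spacing = self.volumes[0].voxel_size
        for v in self.volumes:
            if v.shape != shape:
                raise ValidationError(f"volume shape mismatch: {v.shape} vs {shape}")
            if v.voxel_size != spacing:
                raise ValidationError("voxel spacing mismatch within series")
        if self.repetitions is not None:
            if len(self.repetitions) != len(self.volumes):
                raise ValidationError("repetitions must have one list per time point")
            for reps in self.repetitions:
                for r in reps:
                    if r.shape != shape:
                        raise ValidationError("repetition volume shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.volumes[0].voxel_size

    def averaged(self) -> "AcquisitionSeries":
        """Collapse repetitions into their arithmetic mean per time point."""
        if self.repetitions is None:
            return self
        vols = [
            Volume(np.mean([r.data for r in reps], axis=0), self.voxel_size)
            for reps in self.repetitions
        ]
        return AcquisitionSeries(vols, self.series_type, self.times_ms.copy())


@dataclass
class LandmarkSet:
    """Named sub-pixel 2D landmarks on one frame (volume / time point).

    ``points`` maps a unique name to ``(x, y, slice_index)``.
    """

    frame_id: str
    points: dict[str, tuple[float, float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[float, float, int]] = {}
        for name, (x, y, s) in self.points.items():
            clean[str(name)] = (float(x), float(y), int(s))
        self.points = clean

    def names(self) -> set[str]:
        return set(self.points)

    def xy(self, names: list[str]) -> np.ndarray:
        return np.array([[self.points[n][0], self.points[n][1]] for n in names], dtype=float)


@dataclass
class RoiSpec:
    """Where to read the white-matter (PGZ) and grey-matter (tectum) ROIs.

    The reference slice sits at the caudal end of the rhombencephalic
    ventricle; ``n_extra_slices`` further slices are read moving rostrally
    (``rostral_direction`` = -1 or +1 along the slice axis). Each measured
    slice carries a ``(pgz_center, tectum_center)`` pair of sub-pixel
    coordinates; the ROI is the ``roi_size`` x ``roi_size`` pixel block whose
    upper-left corner is ``round(center - (roi_size - 1) / 2)``.
    """

    reference_slice: int
    centers: dict[int, tuple[tuple[float, float], tuple[float, float]]]
    n_extra_slices: int = 2
    rostral_direction: int = -1
    roi_size: int = 2

    def __post_init__(self) -> None:
        if self.roi_size < 1:
            raise ValidationError("roi_size must be >= 1")
        if self.rostral_direction not in (-1, 1):
            raise ValidationError("rostral_direction must be -1 or +1")
        if self.n_extra_slices < 0:
            raise ValidationError("n_extra_slices must be >= 0")
        missing = [s for s in self.slice_indices() if s not in self.centers]
        if missing:
            raise ValidationError(f"no ROI centers for slices {missing}")

    def slice_indices(self) -> list[int]:
        return [self.reference_slice + i * self.rostral_direction
                for i in range(self.n_extra_slices + 1)]

    @classmethod
    def with_shared_centers(cls, reference_slice: int,
                            pgz_center: tuple[float, float],
                            tectum_center: tuple[float, float],
                            n_extra_slices: int = 2,
                            rostral_direction: int = -1,
                            roi_size: int = 2) -> "RoiSpec":
        """Reuse one (PGZ, tectum) center pair on every measured slice."""
        idx = [reference_slice + i * rostral_direction for i in range(n_extra_slices + 1)]
        centers = {s: (tuple(pgz_center), tuple(tectum_center)) for s in idx}
        return cls(reference_slice, centers, n_extra_slices, rostral_direction, roi_size)


@dataclass
class FiberContourPair:
    """Paired closed polygons for one nerve fiber: axon boundary inside the
    myelin outer boundary. Vertices are (x, y) in ``unit`` length units;
    closure is implicit (last vertex connects back to the first)."""

    fiber_id: str
    axon: np.ndarray
    myelin: np.ndarray

    def __post_init__(self) -> None:
        self.axon = _validate_contour(np.asarray(self.axon, float), f"{self.fiber_id}/axon")
        self.myelin = _validate_contour(np.asarray(self.myelin, float), f"{self.fiber_id}/myelin")
        if not shapely.contains_properly(Polygon(self.myelin), Polygon(self.axon)):
            raise ValidationError(
                f"fiber {self.fiber_id}: axon contour is not strictly inside the myelin contour")


@dataclass
class FiberContourTable:
    fibers: list[FiberContourPair]
    unit: str = "nm"

    def __post_init__(self) -> None:
        if self.unit not in ("nm", "um"):
            raise ValidationError(f"unit must be 'nm' or 'um', got {self.unit!r}")


def _validate_contour(verts: np.ndarray, label: str) -> np.ndarray:
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValidationError(f"contour {label}: need >= 3 (x, y) vertices")
    if not np.all(np.isfinite(verts)):
        raise ValidationError(f"contour {label}: non-finite vertex")
    poly = Polygon(verts)
    if not poly.is_valid or poly.area <= 0:
        raise ValidationError(f"contour {label}: polygon is self-intersecting or degenerate")
    return verts


# ---------------------------------------------------------------------------
# Volume / series I/O
# ---------------------------------------------------------------------------

def write_volume(vol: Volume, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(list(vol.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float64), affine), str(path))
    return path


def read_volume(path: str | Path) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing)


def write_series(series: AcquisitionSeries, out_dir: str | Path) -> Path:
    """Write one NIfTI per time point (and per repetition) plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = series.series_type.lower()
    names = []
    for i, vol in enumerate(series.volumes):
        name = f"{prefix}_{i:03d}.nii.gz"
        write_volume(vol, out_dir / name)
        names.append(name)
    manifest: dict = {
        "series_type": series.series_type,
        "times_ms": [float(t) for t in series.times_ms],
        "voxel_size_mm": list(series.voxel_size),
        "volumes": names,
    }
    if series.repetitions is not None:
        rep_names = []
        for i, reps in enumerate(series.repetitions):
            row = []
            for j, rep in enumerate(reps):
                name = f"{prefix}_{i:03d}_rep{j:02d}.nii.gz"
                write_volume(rep, out_dir / name)
                row.append(name)
            rep_names.append(row)
        manifest["repetitions"] = rep_names
    (out_dir / SERIES_MANIFEST).write_text(json.dumps(manifest, indent=2))
    return out_dir / SERIES_MANIFEST


def read_series(path: str | Path) -> AcquisitionSeries:
    """Read a series from a manifest file or a directory containing one."""
    path = Path(path)
    manifest_path = path / SERIES_MANIFEST if path.is_dir() else path
    if not manifest_path.exists():
        raise FormatError(f"series manifest not found: {manifest_path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"unreadable series manifest {manifest_path}: {e}") from e
    for key in ("series_type", "times_ms", "volumes"):
        if key not in manifest:
            raise FormatError(f"series manifest missing required key {key!r}")
    base = manifest_path.parent
    # voxel spacing comes from the manifest: NIfTI headers store zooms as
    # float32, which would break exact round-tripping
    vs = tuple(manifest.get("voxel_size_mm", ())) or None

    def _load(name):
        vol = read_volume(base / name)
        return Volume(vol.data, vs) if vs else vol

    volumes = [_load(name) for name in manifest["volumes"]]
    reps = None
    if "repetitions" in manifest:
        reps = [[_load(n) for n in row] for row in manifest["repetitions"]]
    return AcquisitionSeries(volumes, manifest["series_type"],
                             np.asarray(manifest["times_ms"], float), reps)


# ---------------------------------------------------------------------------
# Landmark tables
# ---------------------------------------------------------------------------

LANDMARK_COLUMNS = ["frame_id", "name", "x", "y", "slice"]


def write_landmarks(sets: dict[str, LandmarkSet] | list[LandmarkSet], path: str | Path) -> Path:
    if isinstance(sets, dict):
        sets = list(sets.values())
    rows = []
    for lm in sets:
        for name, (x, y, s) in lm.points.items():
            rows.append((lm.frame_id, name, x, y, s))
    df = pd.DataFrame(rows, columns=LANDMARK_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_landmarks(path: str | Path) -> dict[str, LandmarkSet]:
    """Read a landmark TSV, grouped by ``frame_id``. Empty file -> empty dict."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        warnings.warn(f"landmark table {path} is empty", stacklevel=2)
        return {}
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"landmark table missing columns {sorted(missing)}")
    if df.empty:
        warnings.warn(f"landmark table {path} has no rows", stacklevel=2)
        return {}
    out: dict[str, LandmarkSet] = {}
    for frame_id, grp in df.groupby("frame_id", sort=False):
        if grp["name"].duplicated().any():
            dup = grp.loc[grp["name"].duplicated(), "name"].iloc[0]
            raise ValidationError(f"duplicate landmark {dup!r} in frame {frame_id!r}")
        pts = {row["name"]: (row["x"], row["y"], int(row["slice"]))
               for _, row in grp.iterrows()}
        out[str(frame_id)] = LandmarkSet(str(frame_id), pts)
    return out


# ---------------------------------------------------------------------------
# Fiber contour tables
# ---------------------------------------------------------------------------

CONTOUR_COLUMNS = ["fiber_id", "boundary", "vertex_order", "x", "y"]


def write_contours(table: FiberContourTable, path: str | Path) -> Path:
    rows = []
    for fib in table.fibers:
        for boundary, verts in (("axon", fib.axon), ("myelin", fib.myelin)):
            for k, (x, y) in enumerate(verts):
                rows.append((fib.fiber_id, boundary, k, x, y))
    df = pd.DataFrame(rows, columns=CONTOUR_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# unit: {table.unit}\n")
        df.to_csv(fh, sep="\t", index=False)
    return Path(path)


def read_contours(path: str | Path, unit: str | None = None) -> FiberContourTable:
    """Read a fiber contour TSV. The length unit comes from a leading
    ``# unit:`` comment line unless overridden by the ``unit`` argument."""
    path = Path(path)
    file_unit = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#"):
        if "unit:" in first:
            file_unit = first.split("unit:")[1].strip()
    unit = unit or file_unit
    if unit is None:
        raise FormatError(f"{path}: no '# unit:' header line and no unit argument")
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(CONTOUR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"contour table missing columns {sorted(missing)}")
    fibers = []
    for fiber_id, grp in df.groupby("fiber_id", sort=False):
        boundaries = set(grp["boundary"])
        if boundaries != {"axon", "myelin"}:
            raise ValidationError(
                f"fiber {fiber_id!r}: need exactly one axon and one myelin boundary, "
                f"got {sorted(boundaries)}")
        parts = {}
        for boundary, sub in grp.groupby("boundary"):
            sub = sub.sort_values("vertex_order")
            parts[boundary] = sub[["x", "y"]].to_numpy(float)
        fibers.append(FiberContourPair(str(fiber_id), parts["axon"], parts["myelin"]))
    return FiberContourTable(fibers, unit=unit)


# ---------------------------------------------------------------------------
# ROI spec (YAML)
# ---------------------------------------------------------------------------

def write_roi_spec(spec: RoiSpec, path: str | Path) -> Path:
    doc = {
        "reference_slice": spec.reference_slice,
        "n_extra_slices": spec.n_extra_slices,
        "rostral_direction": spec.rostral_direction,
        "roi_size": spec.roi_size,
        "slices": [
            {"slice_index": s,
             "pgz_center": [float(c) for c in spec.centers[s][0]],
             "tectum_center": [float(c) for c in spec.centers[s][1]]}
            for s in spec.slice_indices()
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
    return Path(path)


def read_roi_spec(path: str | Path) -> RoiSpec:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise FormatError(f"unreadable ROI spec {path}: {e}") from e
    if not isinstance(doc, dict) or "reference_slice" not in doc:
        raise FormatError(f"ROI spec {path} missing 'reference_slice'")
    centers = {}
    if "slices" in doc:
        for entry in doc["slices"]:
            centers[int(entry["slice_index"])] = (
                tuple(entry["pgz_center"]), tuple(entry["tectum_center"]))
    elif "pgz_center" in doc and "tectum_center" in doc:
        return RoiSpec.with_shared_centers(
            int(doc["reference_slice"]),
            tuple(doc["pgz_center"]), tuple(doc["tectum_center"]),
            int(doc.get("n_extra_slices", 2)),
            int(doc.get("rostral_direction", -1)),
            int(doc.get("roi_size", 2)))
    else:
        raise FormatError(f"ROI spec {path}: need 'slices' or shared center pair")
    return RoiSpec(int(doc["reference_slice"]), centers,
                   int(doc.get("n_extra_slices", 2)),
                   int(doc.get("rostral_direction", -1)),
                   int(doc.get("roi_size", 2)))


# ---------------------------------------------------------------------------
# Parameter map I/O (planes + hyperparameter sidecar)
# ---------------------------------------------------------------------------

PARAMETER_MAP_SIDECAR = "parameter_map.json"


def write_parameter_map(pmap, out_dir: str | Path) -> Path:
    """Write a fitted ParameterMap as one NIfTI per plane plus a JSON sidecar
    recording the fit hyperparameters and model conventions."""
    from .relaxometry import ParameterMap  # local import to avoid a cycle

    if not isinstance(pmap, ParameterMap):
        raise ValidationError("write_parameter_map expects a ParameterMap")
    pmap.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vs = pmap.voxel_size
    planes = {
        "m0": pmap.m0.astype(np.float64),
        "t_value": pmap.t_value.astype(np.float64),
        "converged": pmap.converged.astype(np.uint8),
        "iterations": pmap.iterations.astype(np.int32),
        "sse": pmap.sse.astype(np.float64),
        "mask": pmap.mask.astype(np.uint8),
    }
    affine = np.diag(list(vs) + [1.0])
    for name, arr in planes.items():
        nib.save(nib.Nifti1Image(arr, affine), str(out_dir / f"{name}.nii.gz"))
    sidecar = {
        "series_type": pmap.series_type,
        "voxel_size_mm": list(vs),
        "hyperparams": pmap.hyperparams.to_dict(),
        "conventions": {
            "exponent_sign": "negative",
            "loss": "sum_of_squared_residuals",
            "t1_model": "S = M0 * (1 - exp(-TR/T1))",
            "t2_model": "S = M0 * exp(-TE/T2)",
        },
    }
    (out_dir / PARAMETER_MAP_SIDECAR).write_text(json.dumps(sidecar, indent=2))
    return out_dir


def read_parameter_map(path: str | Path):
    from .relaxometry import FitHyperparams, ParameterMap

    path = Path(path)
    sidecar_path = path / PARAMETER_MAP_SIDECAR
    if not sidecar_path.exists():
        raise FormatError(f"parameter map sidecar not found: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())

    def plane(name, dtype):
        img = nib.load(str(path / f"{name}.nii.gz"))
        return np.asanyarray(img.dataobj).astype(dtype)

    return ParameterMap(
        m0=plane("m0", np.float64),
        t_value=plane("t_value", np.float64),
        converged=plane("converged", bool),
        iterations=plane("iterations", np.int64),
        sse=plane("sse", np.float64),
        mask=plane("mask", bool),
        hyperparams=FitHyperparams(**sidecar["hyperparams"]),
        series_type=sidecar["series_type"],
        voxel_size=tuple(sidecar["voxel_size_mm"]),
    )
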