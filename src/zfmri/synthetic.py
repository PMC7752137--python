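"""Ground-truth-known synthetic data for every pipeline stage.

A digital "fish head" phantom stands in for the undeposited specimens: an
ellipsoidal skull shell around an ellipsoidal brain with a periventricular
white-matter band, each compartment carrying piecewise-constant (M0, T1, T2).
Series are imaged with the study's acquisition timing (TR = [50, 150, 275,
450, 600] ms with four repetitions; TE = [12.2, 36.6, 60.94] ms with nine
repetitions), corrupted by per-acquisition in-plane rigid motion and Rician
magnitude noise. Cohorts draw per-specimen biological variability around
group-level deltas (mutant brains smaller, white-matter T2 elevated), and
fiber contour sets are concentric (optionally elliptical) polygon pairs with
exactly known G-ratios.

The default grid is a desk-scale 48 x 24 x 28 at 0.22 mm voxels — anatomy
proportions preserved, not the native acquisition matrix — so the full suite
runs in minutes; the native-scale grid remains constructible by config.
All randomness flows from explicit integer seeds via ``numpy``
``SeedSequence`` spawning; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .io import (AcquisitionSeries, FiberContourPair, FiberContourTable,
                 LandmarkSet, RoiSpec, Volume)
from .registration import RigidTransform2D
from .relaxometry import t1_signal, t2_signal

logger = logging.getLogger(__name__)

__all__ = ["Compartment", "PhantomSpec", "Phantom", "GroupDeltas",
           "SimulatedSeries", "SyntheticDataset",
           "make_phantom", "smooth_phantom", "simulate_series", "simulate_t2w_volume",
           "rician", "simulate_cohort", "simulate_morphometry_cohort",
           "make_fiber_set",
           "T1_TIMES_MS", "T2_TIMES_MS"]

# acquisition timing of the study the generator emulates
T1_TIMES_MS = (50.0, 150.0, 275.0, 450.0, 600.0)
T2_TIMES_MS = (12.2, 36.6, 60.94)
T1_REPETITIONS = 4
T2_REPETITIONS = 9


@dataclass
class Compartment:
    """Piecewise-constant tissue parameters: M0 (signal units), T1/T2 (ms)."""

    m0: float
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if self.m0 < 0 or self.t1 <= 0 or self.t2 <= 0:
            raise ValidationError("compartment needs m0 >= 0 and T1, T2 > 0")


@dataclass
class PhantomSpec:
    """Geometry, tissue parameters and acquisition settings of one phantom.

    Sizes are in mm; the skull is an ellipsoidal shell whose outer left-right
    extent defines ``skull_width_mm``, the morphometry normalizer. Tissue
    values are configuration choices placed so the TR/TE sets straddle the
    compartment T1/T2; M0 sits at the fitter's native signal scale.
    """

    shape: tuple[int, int, int] = (48, 24, 28)
    voxel_size_mm: float = 0.22
    skull_width_mm: float = 4.30
    brain_length_mm: float = 4.55   # rostro-caudal (slice axis)
    brain_width_mm: float = 3.09    # left-right
    brain_height_mm: float = 2.65   # dorso-ventral
    skull_thickness_mm: float = 0.22
    grey: Compartment = field(default_factory=lambda: Compartment(8000.0, 150.0, 75.0))
    white: Compartment = field(default_factory=lambda: Compartment(8000.0, 110.0, 45.0))
    skull: Compartment = field(default_factory=lambda: Compartment(1500.0, 300.0, 20.0))
    noise_sigma: float = 170.0      # signal units; ~peak T2w signal / 40
    motion_amplitude_px: float = 0.5
    motion_amplitude_deg: float = 0.3
    t1_times_ms: tuple = T1_TIMES_MS
    t2_times_ms: tuple = T2_TIMES_MS
    t1_repetitions: int = T1_REPETITIONS
    t2_repetitions: int = T2_REPETITIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 8:
            raise ValidationError("phantom grid must be 3D with every axis >= 8")
        if self.voxel_size_mm <= 0:
            raise ValidationError("voxel_size_mm must be > 0")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")
        for name in ("skull_width_mm", "brain_length_mm", "brain_width_mm",
                     "brain_height_mm", "skull_thickness_mm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        vx = self.voxel_size_mm
        margin = 0.5  # voxels of CSF gap between brain and skull shell
        inner_x = self.skull_width_mm / (2 * vx) - self.skull_thickness_mm / vx
        if self.brain_width_mm / (2 * vx) + margin > inner_x:
            raise ValidationError("brain does not fit inside the skull shell (width)")
        nx, ny, nz = self.shape
        if (self.brain_length_mm / (2 * vx) + self.skull_thickness_mm / vx + margin
                > (nz - 1) / 2):
            raise ValidationError("skull does not fit inside the grid (length)")
        if (self.brain_height_mm / (2 * vx) + self.skull_thickness_mm / vx + margin
                > (ny - 1) / 2):
            raise ValidationError("skull does not fit inside the grid (height)")
        if self.skull_width_mm / (2 * vx) > (nx - 1) / 2:
            raise ValidationError("skull does not fit inside the grid (width)")

    # --- derived geometry, all in voxel units -----------------------------
    @property
    def center(self) -> tuple[float, float, float]:
        return tuple((n - 1) / 2.0 for n in self.shape)

    @property
    def brain_semi_axes(self) -> tuple[float, float, float]:
        vx = self.voxel_size_mm
        return (self.brain_width_mm / (2 * vx),
                self.brain_height_mm / (2 * vx),
                self.brain_length_mm / (2 * vx))

    @property
    def skull_outer_semi_axes(self) -> tuple[float, float, float]:
        vx = self.voxel_size_mm
        bx, by, bz = self.brain_semi_axes
        gap = 0.5 + self.skull_thickness_mm / vx
        return (self.skull_width_mm / (2 * vx), by + gap, bz + gap)


@dataclass
class Phantom:
    """Realized phantom: truth maps, masks, landmark tables and ROI spec."""

    spec: PhantomSpec
    m0: Volume | None
    t1: Volume | None
    t2: Volume | None
    masks: dict[str, np.ndarray]
    morpho_landmarks: LandmarkSet
    reg_landmarks: LandmarkSet
    roi_spec: RoiSpec
    truth: dict

    def expected_roi_ratio(self, te_ms: float) -> float:
        """Closed-form noise-free PGZ/tectum T2w ratio at echo time ``te_ms``."""
        s = self.spec
        return float((s.white.m0 * math.exp(-te_ms / s.white.t2))
                     / (s.grey.m0 * math.exp(-te_ms / s.grey.t2)))


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    x, y, z = np.ogrid[:shape[0], :shape[1], :shape[2]]
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
            + ((z - cz) / az) ** 2) <= 1.0


def make_phantom(spec: PhantomSpec, volumes: bool = True) -> Phantom:
    """Build truth maps, compartment masks, landmarks and the ROI spec.

    Deterministic given ``spec``; with ``volumes=False`` only geometry and
    tables are produced (fast path for landmark-level simulations).
    """
    cx, cy, cz = spec.center
    brain = _ellipsoid(spec.shape, spec.center, spec.brain_semi_axes)
    skull_outer = _ellipsoid(spec.shape, spec.center, spec.skull_outer_semi_axes)
    vx = spec.voxel_size_mm
    t_vox = spec.skull_thickness_mm / vx
    inner_axes = tuple(a - t_vox for a in spec.skull_outer_semi_axes)
    skull_inner = _ellipsoid(spec.shape, spec.center, inner_axes)
    skull_mask = skull_outer & ~skull_inner

    # periventricular white-matter band near the dorsal brain surface,
    # spanning the ROI slices
    bx, by, bz = spec.brain_semi_axes
    roi_ref = int(round(cz + 0.35 * bz))
    x, y, z = np.ogrid[:spec.shape[0], :spec.shape[1], :spec.shape[2]]
    band = ((np.abs(x - cx) <= 2.5) & (np.abs(y - (cy - 3.0)) <= 1.5)
            & (z >= roi_ref - 3) & (z <= roi_ref))
    white_mask = brain & band
    grey_mask = brain & ~white_mask

    m0_map = t1_map = t2_map = None
    if volumes:
        m0 = np.zeros(spec.shape)
        t1 = np.ones(spec.shape)  # positive filler outside tissue; masked out downstream
        t2 = np.ones(spec.shape)
        for mask, comp in ((skull_mask, spec.skull), (grey_mask, spec.grey),
                           (white_mask, spec.white)):
            m0[mask], t1[mask], t2[mask] = comp.m0, comp.t1, comp.t2
        vs = (vx, vx, vx)
        m0_map, t1_map, t2_map = Volume(m0, vs), Volume(t1, vs), Volume(t2, vs)

    sx = spec.skull_outer_semi_axes[0]
    rep_slice = int(round(cz))
    morpho = LandmarkSet("morpho", {
        "olfactory_tip": (cx, cy, int(round(cz - bz))),
        "tectum_end": (cx, cy, int(round(cz + bz))),
        "tectum_left": (cx - bx, cy, rep_slice),
        "tectum_right": (cx + bx, cy, rep_slice),
        "brain_top": (cx, cy - by, rep_slice),
        "brain_bottom": (cx, cy + by, rep_slice),
        "skull_left": (cx - sx, cy, rep_slice),
        "skull_right": (cx + sx, cy, rep_slice),
    })
    reg = LandmarkSet("reference", {
        "lens_left": (cx - 6.0, cy - 2.0, rep_slice),
        "lens_right": (cx + 6.0, cy - 2.0, rep_slice),
        "vagal_lobe_tip": (cx, cy + 5.0, rep_slice),
    })
    roi_spec = RoiSpec.with_shared_centers(
        reference_slice=roi_ref, pgz_center=(cx, cy - 3.0),
        tectum_center=(cx, cy + 3.0), n_extra_slices=2, rostral_direction=-1,
        roi_size=2)

    truth = {
        "skull_width_mm": spec.skull_width_mm,
        "brain_length_mm": spec.brain_length_mm,
        "brain_width_mm": spec.brain_width_mm,
        "brain_height_mm": spec.brain_height_mm,
        "normalized_length": spec.brain_length_mm / spec.skull_width_mm,
        "normalized_width": spec.brain_width_mm / spec.skull_width_mm,
        "normalized_height": spec.brain_height_mm / spec.skull_width_mm,
        "grey": vars(spec.grey).copy(),
        "white": vars(spec.white).copy(),
        "roi_reference_slice": roi_ref,
    }
    masks = {"brain": brain, "grey": grey_mask, "white": white_mask,
             "skull": skull_mask, "background": ~(brain | skull_outer)}
    return Phantom(spec, m0_map, t1_map, t2_map, masks, morpho, reg, roi_spec, truth)


def smooth_phantom(phantom: Phantom, sigma_vox: float = 1.5) -> Phantom:
    """Gaussian-smooth the truth maps, turning the piecewise-constant phantom
    into a spatially smooth one (used to study resampling fidelity, where
    bilinear interpolation of smooth fields is near-exact)."""
    from scipy.ndimage import gaussian_filter

    if phantom.m0 is None:
        raise ValidationError("phantom was built without volumes")
    if sigma_vox <= 0:
        raise DomainError("sigma_vox must be > 0")
    vs = phantom.m0.voxel_size
    sm = {name: Volume(gaussian_filter(getattr(phantom, name).data, sigma_vox), vs)
          for name in ("m0", "t1", "t2")}
    return Phantom(phantom.spec, sm["m0"], sm["t1"], sm["t2"], phantom.masks,
                   phantom.morpho_landmarks, phantom.reg_landmarks,
                   phantom.roi_spec, phantom.truth)


def rician(noiseless: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: sqrt((S + n1)^2 + n2^2), n1, n2 ~ N(0, sigma^2)."""
    if sigma < 0:
        raise DomainError("noise sigma must be >= 0")
    if sigma == 0:
        return noiseless.copy()
    n1 = rng.normal(0.0, sigma, noiseless.shape)
    n2 = rng.normal(0.0, sigma, noiseless.shape)
    return np.sqrt((noiseless + n1) ** 2 + n2 ** 2)


@dataclass
class SimulatedSeries:
    series: AcquisitionSeries
    true_transforms: list[RigidTransform2D]
    landmarks: dict[str, LandmarkSet]  # frame_id -> landmark set (moved frames)
    noiseless: list[Volume]


def _motion_schedule(spec: PhantomSpec, n: int, rng: np.random.Generator
                     ) -> list[RigidTransform2D]:
    cx, cy, _ = spec.center
    out = [RigidTransform2D(0.0, 0.0, 0.0, center=(cx, cy))]  # reference frame
    for _ in range(n - 1):
        theta = math.radians(rng.normal(0.0, spec.motion_amplitude_deg))
        tx, ty = rng.normal(0.0, spec.motion_amplitude_px, 2)
        out.append(RigidTransform2D(theta, float(tx), float(ty), center=(cx, cy)))
    return out


def simulate_series(phantom: Phantom, series_type: str,
                    times_ms=None, noise_sigma: float | None = None,
                    n_repetitions: int | None = None,
                    motion: bool | list[RigidTransform2D] = False,
                    seed: int = 0) -> SimulatedSeries:
    """Image the phantom at each TR/TE: signal model, then per-time-point
    rigid motion, then Rician noise per repetition.

    ``motion=True`` draws a random sub-pixel schedule from the spec's
    amplitudes (the first time point is the unmoved reference); a list of
    transforms gives explicit control. Landmark tables for each frame carry
    the exactly moved landmark positions.
    """
    from .registration import apply_transform_slicewise  # avoid cycle at import

    spec = phantom.spec
    if phantom.m0 is None:
        raise ValidationError("phantom was built without volumes")
    if series_type not in ("T1", "T2"):
        raise ValidationError("series_type must be 'T1' or 'T2'")
    if times_ms is None:
        times_ms = spec.t1_times_ms if series_type == "T1" else spec.t2_times_ms
    times_ms = np.asarray(times_ms, float)
    if noise_sigma is None:
        noise_sigma = spec.noise_sigma
    if noise_sigma < 0:
        raise DomainError("noise_sigma must be >= 0")
    if n_repetitions is None:
        n_repetitions = spec.t1_repetitions if series_type == "T1" else spec.t2_repetitions

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(seed)]))
    if motion is True:
        transforms = _motion_schedule(spec, len(times_ms), rng)
    elif motion is False or motion is None:
        cx, cy, _ = spec.center
        transforms = [RigidTransform2D(0.0, 0.0, 0.0, center=(cx, cy))
                      for _ in times_ms]
    else:
        transforms = list(motion)
        if len(transforms) != len(times_ms):
            raise ValidationError("need one motion transform per time point")

    vs = phantom.m0.voxel_size
    noiseless, reps, vols, landmark_sets = [], [], [], {}
    for i, (t, tform) in enumerate(zip(times_ms, transforms)):
        if series_type == "T1":
            clean = t1_signal(phantom.m0.data, phantom.t1.data, t)
        else:
            clean = t2_signal(phantom.m0.data, phantom.t2.data, t)
        clean_vol = Volume(clean, vs)
        noiseless.append(clean_vol)
        moved = apply_transform_slicewise(clean_vol, tform)
        rep_list = [Volume(rician(moved.data, noise_sigma, rng), vs)
                    for _ in range(n_repetitions)]
        reps.append(rep_list)
        vols.append(Volume(np.mean([r.data for r in rep_list], axis=0), vs))
        frame_id = f"{series_type.lower()}_{i:03d}"
        landmark_sets[frame_id] = tform.apply_to_landmarks(phantom.reg_landmarks,
                                                           frame_id)
    series = AcquisitionSeries(vols, series_type, times_ms, reps)
    return SimulatedSeries(series, transforms, landmark_sets, noiseless)


def simulate_t2w_volume(phantom: Phantom, te_ms: float = 36.6,
                        noise_sigma: float | None = None,
                        n_repetitions: int = 1, seed: int = 0) -> Volume:
    """One T2-weighted magnitude volume at a single echo time (repetition-
    averaged Rician noise), as read by the ROI intensity stage."""
    spec = phantom.spec
    if noise_sigma is None:
        noise_sigma = spec.noise_sigma
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(seed)]))
    clean = t2_signal(phantom.m0.data, phantom.t2.data, te_ms)
    acc = np.zeros_like(clean)
    for _ in range(max(1, int(n_repetitions))):
        acc += rician(clean, noise_sigma, rng)
    return Volume(acc / max(1, int(n_repetitions)), phantom.m0.voxel_size)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class GroupDeltas:
    """Multiplicative group-level effects applied to the wild-type spec.

    Defaults mirror the study's effect directions and magnitudes: mutant
    brains smaller along every axis and white-matter T2 elevated (which
    raises the white/grey T2w intensity ratio).
    """

    length_scale: float = 0.841
    width_scale: float = 0.873
    height_scale: float = 0.876
    white_t2_scale: float = 1.25

    @classmethod
    def none(cls) -> "GroupDeltas":
        return cls(1.0, 1.0, 1.0, 1.0)


@dataclass
class SyntheticDataset:
    specimen_id: str
    group: str
    phantom: Phantom
    t1: SimulatedSeries | None = None
    t2: SimulatedSeries | None = None


def _specimen_spec(base: PhantomSpec, deltas: GroupDeltas, size_cv: float,
                   t2_cv: float, rng: np.random.Generator, seed: int) -> PhantomSpec:
    # draws clipped at +/- 3 sigma so every specimen stays geometrically valid
    size = (1.0 + size_cv * float(np.clip(rng.normal(), -3, 3))) if size_cv > 0 else 1.0
    t2f = (1.0 + t2_cv * float(np.clip(rng.normal(), -3, 3))) if t2_cv > 0 else 1.0
    white = replace(base.white, t2=base.white.t2 * deltas.white_t2_scale * t2f)
    return replace(
        base,
        brain_length_mm=base.brain_length_mm * deltas.length_scale * size,
        brain_width_mm=base.brain_width_mm * deltas.width_scale * size,
        brain_height_mm=base.brain_height_mm * deltas.height_scale * size,
        white=white,
        seed=seed,
    )


def simulate_cohort(n_per_group: int = 6, seed: int = 0,
                    base_spec: PhantomSpec | None = None,
                    deltas: GroupDeltas | None = None,
                    size_cv: float = 0.05, t2_cv: float = 0.05,
                    with_images: bool = False,
                    motion: bool = False) -> list[SyntheticDataset]:
    """Two-group cohort (wildtype vs mutant) of phantoms with per-specimen
    biological variability; per-specimen seeds spawn from the master seed.

    ``with_images`` additionally simulates the T1 and T2 acquisition series
    for each specimen (slow); otherwise only geometry/truth is built.
    """
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    base = base_spec or PhantomSpec()
    deltas = deltas if deltas is not None else GroupDeltas()
    master = np.random.SeedSequence(int(seed))
    out: list[SyntheticDataset] = []
    for g_idx, (group, d) in enumerate((("wildtype", GroupDeltas.none()),
                                        ("mutant", deltas))):
        for i in range(n_per_group):
            child = np.random.SeedSequence([int(seed), g_idx, i])
            rng = np.random.default_rng(child)
            spec_seed = int(rng.integers(0, 2**31 - 1))
            spec = _specimen_spec(base, d, size_cv, t2_cv, rng, spec_seed)
            phantom = make_phantom(spec, volumes=with_images)
            ds = SyntheticDataset(f"{group}_{i:02d}", group, phantom)
            if with_images:
                ds.t1 = simulate_series(phantom, "T1", motion=motion, seed=1)
                ds.t2 = simulate_series(phantom, "T2", motion=motion, seed=2)
            out.append(ds)
    return out


def simulate_morphometry_cohort(n_per_group: int = 6, length_effect: float = 0.85,
                                cv: float = 0.05, seed: int = 0
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Lightweight cohort for power studies on the normalized brain length.

    Returns the two groups' normalized-length samples as measured through
    the landmark/morphometry path (including slice-index quantization of the
    rostro-caudal endpoints), with a multiplicative ``length_effect`` on the
    mutant group and lognormal-free Gaussian CV on specimen size.
    """
    from .morphometry import measure_brain

    base = PhantomSpec()
    master_values = {"wildtype": [], "mutant": []}
    for g_idx, (group, scale) in enumerate((("wildtype", 1.0),
                                            ("mutant", length_effect))):
        for i in range(n_per_group):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), g_idx, i]))
            d = GroupDeltas(scale, 1.0, 1.0, 1.0)
            spec = _specimen_spec(base, d, cv, 0.0, rng, 0)
            ph = make_phantom(spec, volumes=False)
            vs = (spec.voxel_size_mm,) * 3
            measures = measure_brain(ph.morpho_landmarks, vs)
            master_values[group].append(measures["brain_length"].normalized)
    return (np.array(master_values["wildtype"]), np.array(master_values["mutant"]))


# ---------------------------------------------------------------------------
# Fiber contour sets
# ---------------------------------------------------------------------------

def make_fiber_set(n_fibers: int, g_mean: float = 0.593, g_sd: float = 0.085,
                   mean_outer_diameter: float = 1.0, diameter_cv: float = 0.3,
                   axis_ratio: float = 0.85, n_vertices: int = 64,
                   jitter_sd: float = 0.0, seed: int = 0, unit: str = "um"
                   ) -> tuple[FiberContourTable, pd.DataFrame]:
    """Concentric elliptical contour pairs with known G-ratios.

    Per fiber the true g is drawn from N(g_mean, g_sd) and realized exactly:
    the axon polygon is the myelin polygon scaled by g about the shared
    center (identical vertex angles), so the discretized perimeter ratio
    equals g to machine precision. Radial vertex jitter (fractional SD
    ``jitter_sd``) emulates tracing noise; draws outside (0.05, 0.95) or
    breaking axon-inside-myelin are resampled with a logged count. Default
    (g_mean, g_sd) follow the wild-type group statistics of the study
    (mutants: 0.690 / 0.076).
    """
    if not 0 < g_mean < 1:
        raise ValidationError("g_mean must be in (0, 1)")
    if n_vertices < 8:
        raise ValidationError("n_vertices must be >= 8")
    if n_fibers < 1:
        raise ValidationError("n_fibers must be >= 1")
    rng = np.random.default_rng(int(seed))
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    fibers, rows, resampled = [], [], 0
    for k in range(n_fibers):
        for _attempt in range(100):
            g = float(rng.normal(g_mean, g_sd))
            if not 0.05 < g < 0.95:
                resampled += 1
                continue
            dia = float(mean_outer_diameter
                        * math.exp(rng.normal(0.0, diameter_cv)
                                   - 0.5 * diameter_cv ** 2))
            a = dia / 2.0
            b = a * axis_ratio
            base_x, base_y = a * np.cos(theta), b * np.sin(theta)
            if jitter_sd > 0:
                jm = 1.0 + rng.normal(0.0, jitter_sd, n_vertices)
                ja = 1.0 + rng.normal(0.0, jitter_sd, n_vertices)
            else:
                jm = ja = np.ones(n_vertices)
            myelin = np.column_stack([base_x * jm, base_y * jm])
            axon = np.column_stack([base_x * g * ja, base_y * g * ja])
            try:
                pair = FiberContourPair(f"fiber_{k:05d}", axon, myelin)
            except ValidationError:
                resampled += 1
                continue
            fibers.append(pair)
            rows.append({"fiber_id": pair.fiber_id, "g_true": g,
                         "outer_diameter_true": dia})
            break
        else:
            raise ValidationError(
                f"could not realize fiber {k} after 100 attempts; check g/jitter settings")
    if resampled:
        logger.info("make_fiber_set: resampled %d invalid draws", resampled)
    return FiberContourTable(fibers, unit=unit), pd.DataFrame(rows)
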