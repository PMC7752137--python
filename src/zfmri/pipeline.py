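"""End-to-end orchestration: simulate -> register -> fit -> morpho -> roi ->
gratio -> report, with YAML config, seed fan-out and provenance capture.

Every stage writes into its own subdirectory of the run directory together
with a ``provenance.json`` (config snapshot, derived seed, package version,
wall time). A single master seed is fanned out per stage through
``numpy.random.SeedSequence([master_seed, stage_index])``, so each stage is
independently reproducible; re-running an identical config and seed
reproduces all numeric outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import PipelineError, ValidationError
from .io import (read_landmarks, read_roi_spec, read_series, read_contours,
                 read_volume, write_contours, write_landmarks,
                 write_parameter_map, write_roi_spec, write_series,
                 write_volume, read_parameter_map)
from .morphometry import compare_groups, measure_brain
from .registration import align_series
from .relaxometry import FitHyperparams, fit_map
from .roi import normalized_wm_intensity
from .gratio import compute_table_metrics, summarize_fibers
from .synthetic import (GroupDeltas, PhantomSpec, Compartment, make_fiber_set,
                        make_phantom, simulate_series)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "register", "fit", "morpho", "roi", "gratio", "report")

_KNOWN_KEYS = {"schema_version", "seed", "out_dir", "stages", "phantom",
               "motion", "fit", "roi", "gratio", "compare"}


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML schema version 1)."""

    seed: int = 0
    out_dir: str = "zfmri_run"
    stages: tuple = STAGES
    phantom: dict = field(default_factory=dict)
    motion: bool = True
    fit: dict = field(default_factory=dict)
    roi: dict = field(default_factory=lambda: {"te_ms": 36.6, "flip_ratio": False})
    gratio: dict = field(default_factory=lambda: {
        "n_fibers": 200, "wildtype": {"g_mean": 0.593, "g_sd": 0.085},
        "mutant": {"g_mean": 0.690, "g_sd": 0.076}})

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValidationError(f"unknown stages {unknown}; valid: {list(STAGES)}")
        self.stages = tuple(s for s in STAGES if s in self.stages)
        if "shape" in self.phantom:  # normalize so configs compare/serialize stably
            self.phantom = {**self.phantom, "shape": list(self.phantom["shape"])}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        unknown = set(doc) - _KNOWN_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        version = doc.get("schema_version", 1)
        if version != 1:
            raise ValidationError(f"unsupported schema_version {version}")
        kwargs = {k: doc[k] for k in
                  ("seed", "out_dir", "phantom", "motion", "fit", "roi", "gratio")
                  if k in doc}
        if "stages" in doc:
            kwargs["stages"] = tuple(doc["stages"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["schema_version"] = 1
        return d


def _stage_seed(master: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(master), idx]).generate_state(1)[0] % (2**31))


def _write_provenance(stage_dir: Path, config: RunConfig, stage: str,
                      seed: int, t_start: float) -> None:
    prov = {
        "stage": stage,
        "package_version": __version__,
        "master_seed": int(config.seed),
        "stage_seed": int(seed),
        "config": config.to_dict(),
        "wall_time_s": round(time.monotonic() - t_start, 3),
    }
    (stage_dir / "provenance.json").write_text(json.dumps(prov, indent=2))


def _phantom_spec(config: RunConfig) -> PhantomSpec:
    over = dict(config.phantom)
    for comp in ("grey", "white", "skull"):
        if comp in over and isinstance(over[comp], dict):
            over[comp] = Compartment(**over[comp])
    if "shape" in over:
        over["shape"] = tuple(over["shape"])
    return PhantomSpec(seed=_stage_seed(config.seed, "simulate"), **over)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the selected stages in dependency order.

    A stage failure raises :class:`PipelineError` naming the stage; outputs
    of completed stages are retained.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    for stage in config.stages:
        fn = _STAGE_FUNCS[stage]
        t0 = time.monotonic()
        seed = _stage_seed(config.seed, stage)
        stage_dir = run_dir / stage
        logger.info("running stage %s -> %s", stage, stage_dir)
        try:
            fn(config, run_dir, stage_dir, seed)
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001 - re-raise typed, named
            raise PipelineError(f"stage {stage!r} failed: {e}") from e
        _write_provenance(stage_dir, config, stage, seed, t0)
    return run_dir


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, run_dir: Path, out: Path, seed: int) -> None:
    out.mkdir(parents=True, exist_ok=True)
    spec = _phantom_spec(config)
    phantom = make_phantom(spec)
    for name in ("m0", "t1", "t2"):
        write_volume(getattr(phantom, name), out / f"truth_{name}.nii.gz")
    np.save(out / "brain_mask.npy", phantom.masks["brain"])
    sims = {}
    for stype, sub_seed in (("T1", 1), ("T2", 2)):
        sim = simulate_series(phantom, stype, motion=config.motion, seed=sub_seed)
        write_series(sim.series, out / f"{stype.lower()}_series")
        write_landmarks(sim.landmarks, out / f"{stype.lower()}_landmarks.tsv")
        sims[stype] = sim
    write_landmarks({"morpho": phantom.morpho_landmarks}, out / "morpho_landmarks.tsv")
    write_roi_spec(phantom.roi_spec, out / "roi.yaml")
    g = config.gratio
    rows = []
    for grp_idx, grp in enumerate(("wildtype", "mutant")):
        table, truth = make_fiber_set(int(g.get("n_fibers", 200)),
                                      seed=seed + grp_idx + 1, **g.get(grp, {}))
        write_contours(table, out / f"fibers_{grp}.tsv")
        truth["group"] = grp
        rows.append(truth)
    pd.concat(rows).to_csv(out / "fibers_truth.tsv", sep="\t", index=False)
    truth = dict(phantom.truth)
    truth["voxel_size_mm"] = spec.voxel_size_mm
    truth["expected_roi_ratio_te36.6"] = phantom.expected_roi_ratio(36.6)
    truth["true_transforms"] = {
        stype: [{"theta": t.theta, "tx": t.tx, "ty": t.ty, "center": list(t.center)}
                for t in sims[stype].true_transforms]
        for stype in ("T1", "T2")}
    (out / "truth.json").write_text(json.dumps(truth, indent=2))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(f"stage {stage!r}: missing required input {path}")
    return path


def _stage_register(config: RunConfig, run_dir: Path, out: Path, seed: int) -> None:
    out.mkdir(parents=True, exist_ok=True)
    sim = run_dir / "simulate"
    rows = []
    for stype in ("T1", "T2"):
        series = read_series(_require(sim / f"{stype.lower()}_series", "register"))
        lms = read_landmarks(_require(sim / f"{stype.lower()}_landmarks.tsv", "register"))
        ordered = [lms[f"{stype.lower()}_{i:03d}"] for i in range(len(series.volumes))]
        aligned, tforms = align_series(series, ordered, reference_index=0)
        write_series(aligned, out / f"{stype.lower()}_series")
        for i, t in enumerate(tforms):
            rows.append({"series": stype, "frame": i,
                         "theta_deg": float(np.degrees(t.theta)),
                         "tx": t.tx, "ty": t.ty, "rms_residual": t.rms_residual})
    pd.DataFrame(rows).to_csv(out / "transforms.tsv", sep="\t", index=False)


def _stage_fit(config: RunConfig, run_dir: Path, out: Path, seed: int) -> None:
    out.mkdir(parents=True, exist_ok=True)
    src = run_dir / "register" if (run_dir / "register").exists() else run_dir / "simulate"
    hp = FitHyperparams(**config.fit)
    qc = []
    for stype in ("T1", "T2"):
        series = read_series(_require(src / f"{stype.lower()}_series", "fit"))
        pmap = fit_map(series, hp=hp)
        write_parameter_map(pmap, out / f"{stype.lower()}_map")
        m = pmap.mask
        qc.append({"series": stype, "n_fitted": int(m.sum()),
                   "n_converged": int(pmap.converged[m].sum()),
                   "median_iterations": float(np.median(pmap.iterations[m])),
                   "median_sse": float(np.median(pmap.sse[m]))})
    pd.DataFrame(qc).to_csv(out / "fit_qc.tsv", sep="\t", index=False)


def _stage_morpho(config: RunConfig, run_dir: Path, out: Path, seed: int) -> None:
    out.mkdir(parents=True, exist_ok=True)
    sim = run_dir / "simulate"
    lms = read_landmarks(_require(sim / "morpho_landmarks.tsv", "morpho"))
    truth = json.loads(_require(sim / "truth.json", "morpho").read_text())
    vs = (truth["voxel_size_mm"],) * 3
    measures = measure_brain(lms["morpho"], vs)
    pd.DataFrame([
        {"measure": m.name, "value_mm": m.value_mm, "normalized": m.normalized}
        for m in measures.values()
    ]).to_csv(out / "morpho.tsv", sep="\t", index=False)


def _stage_roi(config: RunConfig, run_dir: Path, out: Path, seed: int) -> None:
    out.mkdir(parents=True, exist_ok=True)
    sim = run_dir / "simulate"
    src = run_dir / "register" if (run_dir / "register").exists() else sim
    series = read_series(_require(src / "t2_series", "roi"))
    spec = read_roi_spec(_require(sim / "roi.yaml", "roi"))
    te = float(config.roi.get("te_ms", 36.6))
    idx = int(np.argmin(np.abs(series.times_ms - te)))
    flip = bool(config.roi.get("flip_ratio", False))
    measurements, summary = normalized_wm_intensity(series.volumes[idx], spec,
                                                    flip_ratio=flip)
    df = pd.DataFrame([{"slice_index": m.slice_index, "pgz_mean": m.pgz_mean,
                        "tectum_mean": m.tectum_mean, "normalized": m.normalized}
                       for m in measurements])
    df.to_csv(out / "roi.tsv", sep="\t", index=False)
    (out / "roi_summary.json").write_text(json.dumps(
        {"te_ms": float(series.times_ms[idx]), "ratio_direction":
         "tectum/pgz" if flip else "pgz/tectum", "summary_mean": summary}, indent=2))


def _stage_gratio(config: RunConfig, run_dir: Path, out: Path, seed: int) -> None:
    out.mkdir(parents=True, exist_ok=True)
    sim = run_dir / "simulate"
    metrics, labels = [], []
    for grp in ("wildtype", "mutant"):
        table = read_contours(_require(sim / f"fibers_{grp}.tsv", "gratio"))
        ms = compute_table_metrics(table)
        metrics.extend(ms)
        labels.extend([grp] * len(ms))
    pd.DataFrame([{"fiber_id": m.fiber_id, "group": lab, "p_axon": m.p_axon,
                   "p_myelin": m.p_myelin, "g_ratio": m.g_ratio,
                   "axon_diameter": m.axon_diameter,
                   "myelin_thickness": m.myelin_thickness}
                  for m, lab in zip(metrics, labels)]
                 ).to_csv(out / "fiber_metrics.tsv", sep="\t", index=False)
    summaries, comparison = summarize_fibers(metrics, labels)
    doc = {lab: dataclasses.asdict(s) for lab, s in summaries.items()}
    if comparison is not None:
        doc["comparison"] = dataclasses.asdict(comparison)
    (out / "gratio_summary.json").write_text(json.dumps(doc, indent=2))


def _stage_report(config: RunConfig, run_dir: Path, out: Path, seed: int) -> None:
    report_rows, md = build_report(run_dir, config)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(report_rows).to_csv(out / "report.tsv", sep="\t", index=False)
    (out / "report.md").write_text(md)


_STAGE_FUNCS = {
    "simulate": _stage_simulate, "register": _stage_register, "fit": _stage_fit,
    "morpho": _stage_morpho, "roi": _stage_roi, "gratio": _stage_gratio,
    "report": _stage_report,
}


def build_report(run_dir: str | Path, config: RunConfig | None = None
                 ) -> tuple[list[dict], str]:
    """Truth-vs-estimate summary of a completed run (TSV rows + markdown)."""
    run_dir = Path(run_dir)
    sim = run_dir / "simulate"
    missing = [s for s in ("simulate", "fit", "morpho", "roi", "gratio")
               if not (run_dir / s).exists()]
    if missing:
        raise PipelineError(f"report: run is missing stages {missing}")
    truth = json.loads((sim / "truth.json").read_text())
    rows: list[dict] = []

    mask = np.load(sim / "brain_mask.npy")
    for stype in ("T1", "T2"):
        tmap = read_volume(sim / f"truth_{stype.lower()}.nii.gz").data
        pmap = read_parameter_map(run_dir / "fit" / f"{stype.lower()}_map")
        m = pmap.mask & mask
        err = np.abs(pmap.t_value[m] - tmap[m]) / tmap[m]
        rows.append({"stage": "fit", "quantity": f"median_abs_rel_{stype}_error",
                     "value": float(np.median(err)), "truth": 0.0})

    if (run_dir / "register").exists():
        est = pd.read_csv(run_dir / "register" / "transforms.tsv", sep="\t")
        for stype in ("T1", "T2"):
            true_t = truth["true_transforms"][stype]
            sub = est[est["series"] == stype].sort_values("frame")
            terr = [abs(r.tx - (-t["tx"])) + abs(r.ty - (-t["ty"]))
                    for (_, r), t in zip(sub.iterrows(), true_t)]
            rows.append({"stage": "register",
                         "quantity": f"max_translation_error_px_{stype}",
                         "value": float(np.max(terr)), "truth": 0.0})
    else:
        rows.append({"stage": "register", "quantity": "skipped",
                     "value": float("nan"), "truth": float("nan")})

    morpho = pd.read_csv(run_dir / "morpho" / "morpho.tsv", sep="\t")
    for name in ("length", "width", "height"):
        mrow = morpho[morpho["measure"] == {"length": "brain_length",
                                            "width": "tectum_width",
                                            "height": "brain_height"}[name]]
        rows.append({"stage": "morpho", "quantity": f"normalized_{name}",
                     "value": float(mrow["normalized"].iloc[0]),
                     "truth": truth[f"normalized_{name}"]})

    roi_summary = json.loads((run_dir / "roi" / "roi_summary.json").read_text())
    rows.append({"stage": "roi", "quantity": "normalized_wm_intensity",
                 "value": roi_summary["summary_mean"],
                 "truth": truth["expected_roi_ratio_te36.6"]})

    gsum = json.loads((run_dir / "gratio" / "gratio_summary.json").read_text())
    gcfg = (config.gratio if config else
            {"wildtype": {"g_mean": 0.593}, "mutant": {"g_mean": 0.690}})
    for grp in ("wildtype", "mutant"):
        rows.append({"stage": "gratio", "quantity": f"g_ratio_mean_{grp}",
                     "value": gsum[grp]["mean"],
                     "truth": gcfg.get(grp, {}).get("g_mean")})

    lines = ["# Pipeline report", "",
             "| stage | quantity | value | truth |",
             "|---|---|---|---|"]
    for r in rows:
        lines.append(f"| {r['stage']} | {r['quantity']} | {r['value']:.6g} | "
                     f"{r['truth'] if r['truth'] is None else format(r['truth'], '.6g')} |")
    return rows, "\n".join(lines) + "\n"
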