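"""End-to-end orchestration: ingest/simulate -> average -> strain -> register
-> classify -> report, with a machine-readable run manifest.

Two entry points:

* :func:`run_pipeline` consumes a :class:`RunConfig` pointing at motion-grid
  CSVs and optional CT point clouds, persists every stage's output under the
  configured directory and writes ``manifest.json``.  When no CT clouds are
  configured the registration, classification and comparison stages are
  marked skipped and the pipeline still produces strain results.
* :func:`run_synthetic_study` runs the same stages in memory on the default
  synthetic phantom, which is how the package validates itself without
  patient data.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .averaging import build_averaged_model
from .core import (
    MotionGrid,
    PointCloud,
    read_motion_grid,
    read_point_cloud,
    write_motion_grid,
)
from .phantom import (
    PhantomSpec,
    generate_phantom,
    make_ct_clouds,
    make_segmentations,
)
from .registration import (
    Bounds,
    RegistrationResult,
    RigidParams,
    apply_transform,
    icp,
    select_best_frame,
)
from .regions import (
    classify_elements,
    default_capture_radius,
    distribution_indices,
    ks_normality,
    mannwhitney_left,
)
from .strain import strain_amplitudes, strain_series

__all__ = ["RunConfig", "run_pipeline", "run_synthetic_study"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    segmentations: list[str] = field(default_factory=list)
    ct_wall: str | None = None
    ct_calcification: str | None = None
    out_dir: str = "run_output"
    n_heights: int | None = None
    m_circ: int = 36
    max_rotation_deg: float = 30.0
    max_translation_mm: float = 20.0
    scale_range: tuple[float, float] = (0.8, 1.2)
    max_shear: float = 0.2
    coverage_threshold: float = 0.5
    capture_radius: float | None = None
    min_patch_elements: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if len(self.segmentations) < 1:
            raise ValueError("config must list at least one segmentation")
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in (0, 1]")
        if self.scale_range[0] <= 0 or self.scale_range[0] > self.scale_range[1]:
            raise ValueError("invalid scale_range")

    def bounds(self) -> Bounds:
        return Bounds(
            max_rotation=math.radians(self.max_rotation_deg),
            max_translation=self.max_translation_mm,
            scale_range=tuple(self.scale_range),
            max_shear=self.max_shear,
        )


def _registration_record(res: RegistrationResult) -> dict:
    p = res.params
    rec = {
        "alpha_deg": math.degrees(p.alpha),
        "beta_deg": math.degrees(p.beta),
        "gamma_deg": math.degrees(p.gamma),
        "translation_mm": [float(v) for v in p.translation],
        "rmse_mm": res.final_rmse,
        "hausdorff_mm": res.hausdorff,
        "hausdorff_moving_to_static_mm": res.hausdorff_moving_to_static,
        "hausdorff_static_to_moving_mm": res.hausdorff_static_to_moving,
        "iterations": res.iterations,
        "converged": res.converged,
        "rmse_trace_mm": [float(v) for v in res.rmse_trace],
    }
    if hasattr(p, "scales"):
        rec["scales"] = [float(v) for v in p.scales]
        rec["shears"] = [float(v) for v in p.shears]
    return rec


def _amplitude_frame(amp_field, labels=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "element": np.arange(amp_field.amp.shape[0]),
            "amp11_pct": amp_field.amp[:, 0] * 100.0,
            "amp22_pct": amp_field.amp[:, 1] * 100.0,
            "valid": amp_field.valid,
        }
    )
    if labels is not None:
        df["coverage"] = labels.coverage
        df["calcified"] = labels.calcified
    return df


def _di_and_tests(amp_field, labels) -> dict:
    report = {"distribution_indices": distribution_indices(amp_field, labels).indices}
    tests = {}
    valid = amp_field.valid
    for name, c in (("longitudinal", 0), ("circumferential", 1)):
        calc = amp_field.amp[valid & labels.calcified, c] * 100.0
        nocalc = amp_field.amp[valid & ~labels.calcified, c] * 100.0
        if calc.size and nocalc.size:
            t = mannwhitney_left(calc, nocalc)
            entry = {
                "u_statistic": t.u_statistic,
                "p_value": t.p_value,
                "stars": t.stars,
                "method": t.method,
                "n_calc": t.n_calc,
                "n_nocalc": t.n_nocalc,
            }
            for label, sample in (("calc", calc), ("nocalc", nocalc)):
                if sample.size >= 5:
                    normal, stat, pv = ks_normality(sample)
                    entry[f"ks_normal_{label}"] = {
                        "normal": normal, "statistic": stat, "p_value": pv,
                    }
            tests[name] = entry
    report["tests"] = tests
    return report


def analyze_models(
    models: dict[str, MotionGrid],
    ct_wall: PointCloud | None,
    ct_calc: PointCloud | None,
    bounds: Bounds | None = None,
    coverage_threshold: float = 0.5,
    capture_radius: float | None = None,
    min_patch_elements: int = 1,
) -> dict:
    """Strain, registration, classification and statistics for named models.

    ``models`` maps a model name (segmentation id or "averaged") to its
    motion grid.  Returns a nested result dict; per-model entries carry the
    amplitude field and, when CT clouds are given, rigid/affine registration
    records, element labels, distribution indices and test results.
    """
    bounds = bounds or Bounds()
    out: dict = {"models": {}}
    for name, grid in models.items():
        entry: dict = {}
        sf = strain_series(grid)
        amp = strain_amplitudes(sf)
        entry["strain_field"] = sf
        entry["amplitudes"] = amp
        if ct_wall is not None:
            best, results = select_best_frame(grid, ct_wall, mode="rigid", bounds=bounds)
            entry["best_frame"] = best
            entry["rigid"] = results[best]
            entry["rigid_record"] = _registration_record(results[best])
            if ct_calc is not None:
                affine = icp(
                    grid.nodes(best), ct_wall, mode="affine", bounds=bounds
                )
                entry["affine"] = affine
                entry["affine_record"] = _registration_record(affine)
                registered = apply_transform(affine.params, grid.nodes(best))
                # the capture radius must absorb the residual wall-to-wall
                # registration error, otherwise no in-plane coverage is seen
                radius = capture_radius
                if radius is None:
                    radius = default_capture_radius(ct_calc) + 2.0 * affine.final_rmse
                labels = classify_elements(
                    sf.mesh,
                    registered,
                    ct_calc,
                    threshold=coverage_threshold,
                    min_patch_elements=min_patch_elements,
                    capture_radius=radius,
                )
                entry["labels"] = labels
                entry["report"] = _di_and_tests(amp, labels)
        out["models"][name] = entry

    if ct_wall is not None:
        single = {
            n: e for n, e in out["models"].items() if n != "averaged" and "rigid" in e
        }
        if single:
            rmses = {n: e["rigid"].final_rmse for n, e in single.items()}
            out["best_segmentation"] = min(rmses, key=rmses.get)
            out["worst_segmentation"] = max(rmses, key=rmses.get)
            out["rigid_rmse_mm"] = rmses
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full file-based workflow and write all artifacts.

    Any stage failure aborts with the stage name; the partial manifest is
    still written.  Stage outputs are pure functions of (inputs, config,
    seed), so the manifest suffices to reproduce the run.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": {**asdict(config), "scale_range": list(config.scale_range)},
        "stages": {},
        "outputs": {},
    }
    stage = "ingest"
    try:
        t0 = time.perf_counter()
        segs = [
            read_motion_grid(p, segmentation_id=f"seg{i:02d}")
            for i, p in enumerate(config.segmentations)
        ]
        ct_wall = read_point_cloud(config.ct_wall, "wall") if config.ct_wall else None
        ct_calc = (
            read_point_cloud(config.ct_calcification, "calcification")
            if config.ct_calcification
            else None
        )
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0, "status": "ok"}

        stage = "average"
        t0 = time.perf_counter()
        models: dict[str, MotionGrid] = {s.segmentation_id: s for s in segs}
        if len(segs) >= 2:
            averaged, _ = build_averaged_model(
                segs, n_H=config.n_heights, m_H=config.m_circ
            )
            models["averaged"] = averaged.grid
            write_motion_grid(averaged.grid, out_dir / "averaged.csv")
            manifest["outputs"]["averaged"] = "averaged.csv"
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0, "status": "ok"}

        stage = "analysis"
        t0 = time.perf_counter()
        results = analyze_models(
            models,
            ct_wall,
            ct_calc,
            bounds=config.bounds(),
            coverage_threshold=config.coverage_threshold,
            capture_radius=config.capture_radius,
            min_patch_elements=config.min_patch_elements,
        )
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0, "status": "ok"}

        stage = "persist"
        t0 = time.perf_counter()
        for name, entry in results["models"].items():
            labels = entry.get("labels")
            _amplitude_frame(entry["amplitudes"], labels).to_csv(
                out_dir / f"amplitudes_{name}.csv", index=False
            )
            manifest["outputs"][f"amplitudes_{name}"] = f"amplitudes_{name}.csv"
            record = {}
            if "rigid_record" in entry:
                record["rigid"] = entry["rigid_record"]
                record["best_frame"] = entry["best_frame"]
            if "affine_record" in entry:
                record["affine"] = entry["affine_record"]
            if "report" in entry:
                record["report"] = entry["report"]
            if record:
                with open(out_dir / f"report_{name}.json", "w") as fh:
                    json.dump(record, fh, indent=2)
                manifest["outputs"][f"report_{name}"] = f"report_{name}.json"
        for key in ("best_segmentation", "worst_segmentation", "rigid_rmse_mm"):
            if key in results:
                manifest[key] = results[key]
        if ct_wall is None:
            manifest["stages"]["registration"] = {"status": "skipped", "reason": "no CT wall cloud"}
        if ct_calc is None:
            manifest["stages"]["classification"] = {"status": "skipped", "reason": "no calcification cloud"}
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0, "status": "ok"}
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def default_ct_transform(seed: int = 0) -> RigidParams:
    """A reproducible small rigid offset between the CT and ultrasound frames."""
    rng = np.random.default_rng(seed)
    angles = rng.uniform(-math.radians(8.0), math.radians(8.0), size=3)
    translation = rng.uniform(-8.0, 8.0, size=3)
    return RigidParams(*angles, translation)


def run_synthetic_study(
    spec: PhantomSpec | None = None,
    seed: int = 0,
    K: int = 10,
    ct_jitter_sd: float = 0.1,
    wall_density: float = 2.0,
    register: bool = True,
    include_singles: bool = True,
) -> dict:
    """Full study on the synthetic phantom: the package's self-validation run.

    Builds the phantom, K noisy segmentations, CT clouds under a known rigid
    transform, the averaged model, strains, registrations, calcified-element
    classification and group statistics.  Returns the in-memory result dict
    of :func:`analyze_models`, augmented with the phantom truth and the true
    CT transform for error bookkeeping.
    """
    spec = spec or PhantomSpec()
    spec = PhantomSpec(**{**asdict_spec(spec), "seed": seed})
    truth = generate_phantom(spec)
    segs = make_segmentations(truth, K=K, seed=seed + 1)
    tf = default_ct_transform(seed + 2)
    ct_wall, ct_calc = make_ct_clouds(
        truth, transform=tf, jitter_sd=ct_jitter_sd, wall_density=wall_density,
        seed=seed + 3,
    )
    averaged, _ = build_averaged_model(segs)
    models: dict[str, MotionGrid] = {"averaged": averaged.grid}
    if include_singles:
        for s in segs:
            models[s.segmentation_id] = s
    else:
        models[segs[0].segmentation_id] = segs[0]
    results = analyze_models(
        models,
        ct_wall if register else None,
        ct_calc if register else None,
    )
    results["truth"] = truth
    results["segmentations"] = segs
    results["ct_transform"] = tf
    results["ct_wall"] = ct_wall
    results["ct_calcification"] = ct_calc
    return results


def asdict_spec(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["calcified_patches"] = spec.calcified_patches
    return d
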