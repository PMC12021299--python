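"""End-to-end pipeline: generate -> filter -> score -> fit -> null-compare.

Stages communicate through on-disk CSV artifacts so each step can be rerun
and inspected independently; a JSON manifest records the configuration
snapshot, seeds, per-stage row counts, wall times, and a SHA-256 checksum of
every file written.  Figures are rendered to SVG and PNG, and the data
behind every figure is also emitted as CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import yaml

from . import __version__
from .inference import (
    binscatter,
    fit_frame_ols,
    fit_lpm_clustered,
    fit_per_camera,
    fits_table,
    winsorize_upper,
)
from .nullmodel import NullModelConfig, compare_observed_to_null, simulate_random_placement
from .proximity import filter_frames, score_dataset
from .scene import GeneratorConfig, generate_dataset

__all__ = ["AnalysisConfig", "NullSweepConfig", "PipelineConfig", "run_generate", "run_full"]

log = logging.getLogger("crowdcontact")


@dataclass
class AnalysisConfig:
    ci_level_person: float = 0.9995
    ci_level_frame: float = 0.995
    n_bins: int = 20
    winsorize: bool = True
    outcomes: tuple[str, ...] = ("violation", "violation2")


@dataclass
class NullSweepConfig:
    areas_m2: tuple[float, ...] = (650.0, 300.0, 150.0)
    aspect_ratio: float = 2.0
    replicates: int = 10_000
    n_values: tuple[int, ...] = tuple(range(2, 68, 5))
    boundary: str = "plain"


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    null: NullSweepConfig = field(default_factory=NullSweepConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str = "results"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        gen = d.get("generator", {})
        if "crowd_range" in gen:
            gen["crowd_range"] = tuple(gen["crowd_range"])
        for key in ("group_size_dist", "within_group_spacing_m"):
            if key in gen:
                gen[key] = tuple(gen[key])
        null = d.get("null", {})
        for key in ("areas_m2", "n_values"):
            if key in null:
                null[key] = tuple(null[key])
        ana = d.get("analysis", {})
        if "outcomes" in ana:
            ana["outcomes"] = tuple(ana["outcomes"])
        return cls(
            generator=GeneratorConfig(**gen),
            null=NullSweepConfig(**null),
            analysis=AnalysisConfig(**ana),
            output_dir=d.get("output_dir", "results"),
            log_level=d.get("log_level", "INFO"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: PipelineConfig):
        self.data = {
            "version": __version__,
            "config": config.to_dict(),
            "seed": config.generator.seed,
            "stages": {},
            "files": {},
        }

    def stage(self, name: str, wall_s: float, **counts) -> None:
        self.data["stages"][name] = {"wall_s": round(wall_s, 3), **counts}

    def file(self, path: Path) -> None:
        self.data["files"][path.name] = {"sha256": _sha256(path), "bytes": path.stat().st_size}

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.data, indent=2, default=str) + "\n")


def _write_csv(df: pd.DataFrame, path: Path, manifest: _Manifest) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest.file(path)


def run_generate(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Generate the detection table and write it (with a manifest) to disk."""
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    t0 = time.perf_counter()
    det = generate_dataset(config.generator)
    path = out / "detections.csv"
    _write_csv(det, path, manifest)
    manifest.stage("generate", time.perf_counter() - t0, detections=len(det),
                   frames=int(len(det.drop_duplicates(["camera_id", "frame_id"]))))
    manifest.write(out / "manifest.json")
    log.info("generated %d detections -> %s", len(det), path)
    return path


def _figures(out: Path, manifest: _Manifest, persons, frames, binned_person,
             binned_cam, comparison) -> None:
    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)

    def save(fig, stem: str) -> None:
        for ext in ("svg", "png"):
            p = figdir / f"{stem}.{ext}"
            fig.savefig(p, dpi=120)
            manifest.file(p)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(binned_person["bin_x_mean"], binned_person["bin_y_mean"], "o-")
    ax.set_xlabel("persons present")
    ax.set_ylabel("P(violation)")
    ax.set_title("Violation probability vs crowding (binned)")
    save(fig, "person_binned")

    fig, ax = plt.subplots(figsize=(5, 4))
    for cam, grp in binned_cam.groupby("camera_id"):
        ax.plot(grp["bin_x_mean"], grp["bin_y_mean"], "-", alpha=0.4, lw=0.8)
    ax.set_xlabel("persons present")
    ax.set_ylabel("P(violation)")
    ax.set_title("Per-camera binned association")
    save(fig, "person_binned_per_camera")

    fig, ax = plt.subplots(figsize=(5, 4))
    fr = frames.groupby("n_present")["n_violators"].mean()
    ax.plot(fr.index, fr.values, "o", ms=3)
    ax.set_xlabel("persons present")
    ax.set_ylabel("violators per frame")
    ax.set_title("Frame-level violations vs crowding")
    save(fig, "frame_violations")

    fig, ax = plt.subplots(figsize=(5, 4))
    for (area, _), grp in comparison.groupby(["area_m2", "boundary"]):
        grp = grp.sort_values("n_present")
        ax.plot(grp["n_present"], grp["null_mean_pairs"], "--", lw=1,
                label=f"null {area:g} m$^2$")
    one = comparison[comparison["area_m2"] == comparison["area_m2"].max()].sort_values("n_present")
    ax.plot(one["n_present"], one["obs_mean_pairs"], "k-", lw=2, label="observed")
    ax.set_xlabel("persons present")
    ax.set_ylabel("violating pairs per frame")
    ax.legend(fontsize=8)
    ax.set_title("Observed vs random-placement null")
    save(fig, "observed_vs_null")


def run_full(config: PipelineConfig) -> dict:
    """Run the whole analysis; returns a dict of the key artifacts in memory."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    ana = config.analysis

    t0 = time.perf_counter()
    det = generate_dataset(config.generator)
    _write_csv(det, out / "detections.csv", manifest)
    manifest.stage("generate", time.perf_counter() - t0, detections=len(det))

    t0 = time.perf_counter()
    filtered, dropped = filter_frames(det)
    _write_csv(filtered, out / "detections_filtered.csv", manifest)
    manifest.stage("filter", time.perf_counter() - t0, detections=len(filtered),
                   frames_dropped=dropped)
    log.info("filter: dropped %d frames with <2 persons", dropped)

    t0 = time.perf_counter()
    persons, frames = score_dataset(filtered, config.generator.threshold_m)
    if len(persons) != len(filtered):
        raise RuntimeError("row-count conservation violated in scoring stage")
    _write_csv(persons, out / "persons.csv", manifest)
    _write_csv(frames, out / "frames.csv", manifest)
    manifest.stage("score", time.perf_counter() - t0, persons=len(persons), frames=len(frames))

    # --- pooled fits: main LPM, camera FE, >=2-contact outcome, winsorized
    t0 = time.perf_counter()
    named = [
        ("lpm_main", fit_lpm_clustered(persons, ci_level=ana.ci_level_person)),
        ("lpm_camera_fe", fit_lpm_clustered(persons, ci_level=ana.ci_level_person,
                                            fixed_effects="camera")),
        ("lpm_violation2", fit_lpm_clustered(persons, outcome="violation2",
                                             ci_level=ana.ci_level_person)),
    ]
    if ana.winsorize:
        wres = winsorize_upper(persons["n_present"].to_numpy())
        pw = persons.assign(n_present_wins=wres.values)
        named.append(("lpm_winsorized",
                      fit_lpm_clustered(pw, predictor="n_present_wins",
                                        ci_level=ana.ci_level_person)))
        manifest.stage("winsorize", 0.0, n_capped=wres.n_capped,
                       upper_fence=wres.upper_fence)
    named.append(("frame_ols", fit_frame_ols(frames, ci_level=ana.ci_level_frame)))
    _write_csv(fits_table(named), out / "fits.csv", manifest)

    # --- per-camera fits
    per_cam = fit_per_camera(persons, frames, ana.ci_level_person, ana.ci_level_frame)
    cam_named = []
    errors = []
    for cf in per_cam:
        if cf.lpm is not None:
            cam_named.append((f"lpm_{cf.camera_id}", cf.lpm))
        if cf.agg is not None:
            cam_named.append((f"ols_{cf.camera_id}", cf.agg))
        if cf.error:
            errors.append({"camera_id": cf.camera_id, "error": cf.error})
    cam_tab = fits_table(cam_named)
    cam_tab.insert(0, "camera_id", [m.split("_", 1)[1] for m in cam_tab["model"]])
    _write_csv(cam_tab, out / "fits_per_camera.csv", manifest)
    if errors:
        _write_csv(pd.DataFrame(errors), out / "fits_per_camera_errors.csv", manifest)

    # --- binned series, pooled and per camera
    bs = binscatter(persons["n_present"], persons["violation"], ana.n_bins)
    binned_person = pd.DataFrame({"bin_x_mean": bs.bin_x_means,
                                  "bin_y_mean": bs.bin_y_means,
                                  "bin_count": bs.bin_counts})
    _write_csv(binned_person, out / "binned_person.csv", manifest)
    cam_parts = []
    for cam, grp in persons.groupby("camera_id", sort=False):
        k = min(ana.n_bins, grp["n_present"].nunique())
        b = binscatter(grp["n_present"], grp["violation"], k)
        cam_parts.append(pd.DataFrame({"camera_id": cam, "bin_x_mean": b.bin_x_means,
                                       "bin_y_mean": b.bin_y_means, "bin_count": b.bin_counts}))
    binned_cam = pd.concat(cam_parts, ignore_index=True)
    _write_csv(binned_cam, out / "binned_person_per_camera.csv", manifest)
    manifest.stage("fit", time.perf_counter() - t0, models=len(named) + len(cam_named))

    # --- null curves and comparison
    t0 = time.perf_counter()
    null_results = []
    curves = []
    for area in config.null.areas_m2:
        nc = NullModelConfig(area_m2=area, aspect_ratio=config.null.aspect_ratio,
                             threshold_m=config.generator.threshold_m,
                             n_values=config.null.n_values,
                             replicates=config.null.replicates,
                             seed=config.generator.seed, boundary=config.null.boundary)
        res = simulate_random_placement(nc)
        null_results.append(res)
        t = res.table.copy()
        t.insert(0, "area_m2", area)
        t["boundary"] = res.boundary
        t["replicates"] = res.replicates
        curves.append(t)
    _write_csv(pd.concat(curves, ignore_index=True), out / "null_curves.csv", manifest)
    comparison = compare_observed_to_null(frames, null_results)
    _write_csv(comparison, out / "observed_vs_null.csv", manifest)
    manifest.stage("null", time.perf_counter() - t0,
                   curves=len(null_results), rows=len(comparison))

    t0 = time.perf_counter()
    _figures(out, manifest, persons, frames, binned_person, binned_cam, comparison)
    manifest.stage("figures", time.perf_counter() - t0)

    manifest.write(out / "manifest.json")
    return {
        "detections": det,
        "persons": persons,
        "frames": frames,
        "fits": fits_table(named),
        "per_camera": per_cam,
        "null_results": null_results,
        "comparison": comparison,
        "output_dir": out,
    }
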