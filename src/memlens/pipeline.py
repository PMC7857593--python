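"""Config-driven analysis pipeline chaining the stages into reproducible runs.

A :class:`RunConfig` names exactly one input source (a trajectory file plus
topology sidecar, or a generator preset), the stages to run, per-stage
parameters, an output directory and a seed.  ``run_pipeline`` executes the
stages in dependency order, writes one CSV table per stage plus a manifest
(inputs, parameters, seed, package version, per-stage SHA-256 checksums),
and is byte-reproducible for identical config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import clustered_fraction_series
from .diffusion import collect_displacements, estimate_D, state_conditioned_D
from .kinetics import site_lifetimes
from .occupancy import occupancy_analysis
from .synthetic import (GeneratorConfig, preset_config, replicate_seeds,
                        simulate_membrane)
from .topography import height_field, mean_curvature
from .trajectory import Trajectory, read_topology, read_trajectory

logger = logging.getLogger(__name__)

ALL_STAGES = ("occupancy", "clusters", "diffusion", "lifetimes", "curvature")
_FLOAT_FMT = "%.8g"


class ConfigurationError(ValueError):
    """Invalid or inconsistent run configuration (raised pre-flight)."""


@dataclass
class RunConfig:
    out_dir: str = "memlens_run"
    seed: int = 0
    log_level: str = "INFO"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # input source: exactly one of (preset, trajectory_path)
    preset: str | None = None
    generator_overrides: dict = field(default_factory=dict)
    n_replicates: int = 1
    trajectory_path: str | None = None
    trajectory_format: str = "csv"
    topology_path: str | None = None
    # per-stage parameters
    cutoff: float = 0.5
    stride: float = 1.0
    windows: list[tuple[float, float]] | None = None
    lag: float = 1.0
    cutoff_bind: float = 0.5
    gap_tolerance: int = 0
    grid: tuple[int, int] = (64, 64)
    smoothing_sigma: float = 1.0
    curvature_mode: str = "small_slope"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**data)
        if cfg.windows is not None:
            cfg.windows = [tuple(w) for w in cfg.windows]
        cfg.grid = tuple(cfg.grid)
        return cfg

    def validate(self) -> None:
        has_preset = self.preset is not None
        has_file = self.trajectory_path is not None
        if has_preset == has_file:
            raise ConfigurationError(
                "exactly one input source required: preset OR trajectory_path")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")


def _generator_config(cfg: RunConfig) -> GeneratorConfig:
    gen = preset_config(cfg.preset, seed=cfg.seed, n_replicates=cfg.n_replicates)
    for key, val in cfg.generator_overrides.items():
        obj = gen
        parts = key.split(".")
        for p in parts[:-1]:
            obj = getattr(obj, p)
        if not hasattr(obj, parts[-1]):
            raise ConfigurationError(f"unknown generator override {key!r}")
        setattr(obj, parts[-1], val)
    if "curvature" in cfg.stages:
        gen.headgroups.enabled = True
    return gen


def _preflight(cfg: RunConfig, gen: GeneratorConfig | None) -> None:
    """Fail before any computation when a stage cannot possibly run."""
    if gen is not None:
        has_tag = gen.n_tag >= 1
        has_res = gen.trap.enabled
        has_site = gen.trap.enabled
        has_hg = gen.headgroups.enabled
    else:
        top = read_topology(cfg.topology_path) if cfg.topology_path else None
        if top is None:
            raise ConfigurationError("file input requires topology_path")
        has_tag = (top.group == "TAG").any()
        has_res = (top.group == "RESIDUE").any()
        has_site = (top.group == "SITE").any()
        has_hg = (top.group == "HEADGROUP").any()
    requirements = {
        "occupancy": [(has_tag, "TAG group"), (has_res, "RESIDUE group")],
        "clusters": [(has_tag, "TAG group")],
        "diffusion": [(has_tag, "TAG group")],
        "lifetimes": [(has_tag, "TAG group"), (has_site, "SITE group")],
        "curvature": [(has_hg, "HEADGROUP group")],
    }
    for stage in cfg.stages:
        for ok, what in requirements[stage]:
            if not ok:
                raise ConfigurationError(
                    f"stage {stage!r} requires a {what} in the topology")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return _sha256(path)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(asctime)s %(levelname)s %(name)s: %(message)s")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gen = _generator_config(cfg) if cfg.preset else None
    _preflight(cfg, gen)

    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "stages": {},
    }

    truth = None
    if gen is not None:
        seeds = replicate_seeds(gen)[: cfg.n_replicates]
        replicates: list[Trajectory] = []
        for rep, s in enumerate(seeds):
            traj, tr = simulate_membrane(gen, seed=s)
            traj.replicate_id = rep
            replicates.append(traj)
            if rep == 0:
                truth = tr
        manifest["source"] = {"preset": cfg.preset, "replicate_seeds": seeds}
        trap_center = np.asarray(gen.trap.center) if gen.trap.enabled else None
    else:
        traj = read_trajectory(cfg.trajectory_path, cfg.trajectory_format,
                               topology_path=cfg.topology_path)
        replicates = [traj]
        manifest["source"] = {"trajectory": cfg.trajectory_path,
                              "topology": cfg.topology_path}
        trap_center = None
    primary = replicates[0]

    try:
        if "occupancy" in cfg.stages:
            windows = cfg.windows or [(primary.times[0],
                                       primary.times[-1] + 1e-9)]
            table = occupancy_analysis(replicates, windows, cutoff=cfg.cutoff,
                                       stride=cfg.stride)
            p = out / "occupancy.csv"
            manifest["stages"]["occupancy"] = {
                "file": p.name, "sha256": _write(table, p),
                "params": {"cutoff": cfg.cutoff, "stride": cfg.stride,
                           "windows": [list(w) for w in windows]}}

        if "clusters" in cfg.stages:
            series = clustered_fraction_series(primary, cutoff=cfg.cutoff,
                                               stride=cfg.stride,
                                               reference=trap_center)
            p = out / "clusters.csv"
            manifest["stages"]["clusters"] = {
                "file": p.name, "sha256": _write(series.to_table(), p),
                "params": {"cutoff": cfg.cutoff, "stride": cfg.stride}}

        if "diffusion" in cfg.stages:
            tag_ids = primary.topology.particles_in_group("TAG")
            rows = []
            if truth is not None and truth.config.trap.enabled:
                sc = state_conditioned_D(primary, tag_ids,
                                         truth.bound_intervals(), lag=cfg.lag)
                for state, est in (("bound", sc.bound), ("free", sc.free)):
                    if est is not None:
                        rows.append(("TAG", state, cfg.lag, est.n, est.D,
                                     est.ci95[0], est.ci95[1], est.fit_ks))
            est = estimate_D(collect_displacements(primary, tag_ids, lag=cfg.lag))
            rows.append(("TAG", "all", cfg.lag, est.n, est.D,
                         est.ci95[0], est.ci95[1], est.fit_ks))
            table = pd.DataFrame(rows, columns=[
                "group", "state", "lag_ns", "n", "D_nm2_per_ns",
                "ci_low", "ci_high", "ks_stat"])
            p = out / "diffusion.csv"
            manifest["stages"]["diffusion"] = {
                "file": p.name, "sha256": _write(table, p),
                "params": {"lag": cfg.lag}}

        if "lifetimes" in cfg.stages:
            stats = site_lifetimes(primary, cutoff_bind=cfg.cutoff_bind,
                                   stride=cfg.stride,
                                   gap_tolerance=cfg.gap_tolerance)
            p = out / "lifetimes.csv"
            sha = _write(stats.events_table(), p)
            _write(stats.survival_table(), out / "survival.csv")
            manifest["stages"]["lifetimes"] = {
                "file": p.name, "sha256": sha,
                "mean_lifetime_ns": (None if np.isnan(stats.mean_lifetime)
                                     else stats.mean_lifetime),
                "params": {"cutoff_bind": cfg.cutoff_bind,
                           "gap_tolerance": cfg.gap_tolerance}}

        if "curvature" in cfg.stages:
            rows = []
            for leaflet in ("UPPER", "LOWER"):
                fld = height_field(primary, leaflet, grid=cfg.grid,
                                   smoothing_sigma=cfg.smoothing_sigma)
                cmap = mean_curvature(fld, mode=cfg.curvature_mode)
                nx, ny = cmap.H.shape
                ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
                rows.append(pd.DataFrame({
                    "leaflet": leaflet, "ix": ix.ravel(), "iy": iy.ravel(),
                    "h_nm": fld.h.ravel(), "H_per_nm": cmap.H.ravel()}))
            table = pd.concat(rows, ignore_index=True)
            p = out / "curvature.csv"
            manifest["stages"]["curvature"] = {
                "file": p.name, "sha256": _write(table, p),
                "sign_convention": "positive_toward_midplane",
                "params": {"grid": list(cfg.grid),
                           "smoothing_sigma": cfg.smoothing_sigma,
                           "mode": cfg.curvature_mode}}
    except Exception as exc:  # record partial completion, then re-raise
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
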