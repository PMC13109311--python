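"""End-to-end pipeline runner: simulate -> extract -> model -> map.

`run_pipeline` chains the package stages under one JSON-style config,
writing every artifact under an output root together with a manifest
(inputs, outputs, seeds, checksums) so deterministic stages can be re-run
and verified bitwise.  Each stochastic stage draws its seed from the global
seed plus the stage name through a stable hash, so stages are individually
reproducible without sharing RNG state.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import canopymap, chemomodels, hsicube, synthdata
from .prep import PrepSpec

__all__ = ["RunConfig", "stage_seed", "run_pipeline", "verify_manifest"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable stage seed: hash of the global seed and the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full demo pipeline run."""

    out_root: str = "runs/demo"
    seed: int = 0
    n_samples: int = 150
    noise_sd: float = 0.01
    nonlinear: bool = False
    canopy_size: int = 48
    gradient: float = 0.1
    grid_preps: tuple = ("none", "ma")
    grid_selectors: tuple = ("lars",)
    grid_splits: tuple = ("spxy",)
    grid_models: tuple = ("plsr",)
    pigments: tuple = ("chla", "chlb", "car", "tpc")

    @staticmethod
    def from_json(path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        cfg = RunConfig(**raw)
        for name in ("grid_preps", "grid_selectors", "grid_splits", "grid_models",
                     "pigments"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the demo pipeline; returns (and writes) the manifest.

    Stages: leaf simulation -> spectra CSV -> model grid -> canopy
    simulation -> ENVI cube -> segmentation -> per-pixel inversion ->
    type summary.  A stage failure raises after persisting the partial
    manifest with the failing stage named.
    """
    root = Path(config.out_root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {**config.__dict__}, "stages": [], "started": time.time()}
    for k, v in list(manifest["config"].items()):
        if isinstance(v, tuple):
            manifest["config"][k] = list(v)

    def record(stage, artifacts, **extra):
        entry = {
            "stage": stage,
            "artifacts": {
                name: {"path": str(p), "sha256": _checksum(Path(p))}
                for name, p in artifacts.items()
            },
            **extra,
        }
        manifest["stages"].append(entry)
        (root / "manifest.json").write_text(json.dumps(manifest, indent=2))

    current = "simulate_leaves"
    try:
        gen_cfg = synthdata.GeneratorConfig(
            n_samples=config.n_samples,
            noise_sd=config.noise_sd,
            nonlinearity=config.nonlinear,
            seed=stage_seed(config.seed, "simulate_leaves"),
        )
        batch = synthdata.simulate_leaf_spectra(gen_cfg)
        spectra_csv = root / "leaf_spectra.csv"
        synthdata.write_spectra_csv(batch, spectra_csv)
        record(current, {"spectra": spectra_csv}, seed=gen_cfg.seed)

        current = "grid"
        grid = chemomodels.run_grid(
            batch.spectra,
            batch.targets,
            batch.wavelengths,
            preps=config.grid_preps,
            selectors=config.grid_selectors,
            splits=config.grid_splits,
            models=config.grid_models,
            pigments=config.pigments,
            seed=stage_seed(config.seed, "grid"),
        )
        grid_csv = root / "grid_results.csv"
        grid.to_csv(grid_csv)
        best_json = root / "grid_best.json"
        best_json.write_text(
            json.dumps({k: {kk: str(vv) for kk, vv in v.items()}
                        for k, v in grid.best.items()}, indent=2)
        )
        record(current, {"table": grid_csv, "best": best_json})

        current = "simulate_canopy"
        canopy_cfg = synthdata.GeneratorConfig(
            noise_sd=0.0, seed=stage_seed(config.seed, "simulate_canopy")
        )
        scene = synthdata.simulate_canopy_cube(
            canopy_cfg, config.canopy_size, config.canopy_size, config.gradient
        )
        cube_path = root / "canopy"
        hsicube.write_envi(scene.cube, cube_path)
        record(
            current,
            {"cube_hdr": cube_path.with_suffix(".hdr"),
             "cube_raw": cube_path.with_suffix(".raw")},
            seed=canopy_cfg.seed,
        )

        current = "segment"
        mask = hsicube.segment_canopy(scene.cube)
        mask_path = root / "canopy_mask"
        hsicube.write_mask(mask, mask_path)
        record(current, {"mask": mask_path.with_suffix(".png"),
                         "provenance": mask_path.with_suffix(".json")})

        current = "map"
        predictors = {}
        from .splitters import spxy

        for pig in ("chla", "chlb", "car"):
            y = batch.target(pig)
            sp = spxy(batch.spectra, y, 0.75)
            predictors[pig] = chemomodels.fit_plsr(
                batch.spectra[sp.calib_idx], y[sp.calib_idx],
                seed=stage_seed(config.seed, f"map_fit_{pig}"),
            )
        pmap = canopymap.invert_canopy(
            scene.cube, mask, predictors, prep=PrepSpec("none")
        )
        map_artifacts = {}
        for plane in pmap.planes:
            out = root / f"map_{plane}"
            canopymap.render_map(pmap, plane, out)
            map_artifacts[f"{plane}_png"] = out.with_suffix(".png")
            map_artifacts[f"{plane}_json"] = out.with_suffix(".json")
        record(current, map_artifacts)

        current = "summarize"
        summary = canopymap.summarize_by_type([pmap], ["demo"])
        summary_csv = root / "type_summary.csv"
        summary.to_csv(summary_csv, index=False)
        record(current, {"summary": summary_csv})
    except Exception as e:
        manifest["failed_stage"] = current
        manifest["error"] = repr(e)
        (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["finished"] = time.time()
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def verify_manifest(manifest_path) -> list:
    """Re-checksum every artifact; returns the list of mismatched paths."""
    manifest = json.loads(Path(manifest_path).read_text())
    bad = []
    for stage in manifest["stages"]:
        for name, art in stage["artifacts"].items():
            p = Path(art["path"])
            if not p.exists() or _checksum(p) != art["sha256"]:
                bad.append(str(p))
    return bad
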