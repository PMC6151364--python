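"""End-to-end orchestration: phantom -> coarse -> initialize -> refine -> evaluate.

One :class:`RunConfig` drives the whole coarse-to-fine chain and a single
seed governs every stochastic stage.  The coarse stage runs in one of two
modes: ``"fcn"`` trains and applies the fusion network, while
``"degraded-truth"`` substitutes a controlled degradation of the ground-truth
mask for the classifier output, so the geometric and deformable stages can be
exercised (and debugged) without any training in the loop.  Every
intermediate artifact is written to the output directory and listed, with a
content hash, in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .core import LabelMask, Volume, write_mask, write_volume
from .fcn import NetConfig, TrainConfig, build_network, predict_stack, slice_volume, train
from .fcn.data import restack
from .initializer import initialize_mesh, rings_to_yaml
from .mesh import TubeMesh
from .metrics import (
    SurfacePair,
    confusion_counts,
    hausdorff_distance,
    mean_surface_distance,
    modified_dice,
    pixel_metrics,
    sample_surface,
)
from .phantom import PhantomSpec, degrade_mask, generate_phantom
from .snake import SnakeParams, evolve, leak_test

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    net: NetConfig = field(default_factory=NetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    snake: SnakeParams = field(default_factory=SnakeParams)
    k: int = 10
    points_per_ring: int = 36
    coarse_mode: str = "degraded-truth"  # or "fcn"
    degrade_kwargs: dict = field(default_factory=dict)
    surface_samples: int = 5000
    seed: int = 0
    output_dir: str = "run_output"

    def __post_init__(self) -> None:
        if self.coarse_mode not in ("fcn", "degraded-truth"):
            raise ValueError("coarse_mode must be 'fcn' or 'degraded-truth'")
        if self.k < 1:
            raise ValueError("resampling interval k must be >= 1")

    def to_yaml(self, path: str | Path) -> Path:
        d = {
            "phantom": asdict(self.phantom),
            "net": asdict(self.net),
            "train": asdict(self.train),
            "snake": asdict(self.snake),
            "k": self.k,
            "points_per_ring": self.points_per_ring,
            "coarse_mode": self.coarse_mode,
            "degrade_kwargs": self.degrade_kwargs,
            "surface_samples": self.surface_samples,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }
        for key in ("grid_shape", "spacing", "cavity_semi_axes"):
            d["phantom"][key] = list(d["phantom"][key])
        d["net"]["skip_streams"] = list(d["net"]["skip_streams"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        ph = d.pop("phantom", {})
        for key in ("grid_shape", "spacing", "cavity_semi_axes"):
            if key in ph:
                ph[key] = tuple(ph[key])
        net = d.pop("net", {})
        if "skip_streams" in net:
            net["skip_streams"] = tuple(net["skip_streams"])
        return cls(
            phantom=PhantomSpec(**ph),
            net=NetConfig(**net),
            train=TrainConfig(**d.pop("train", {})),
            snake=SnakeParams(**d.pop("snake", {})),
            **d,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order and return the metrics report + manifest.

    Artifacts written under ``cfg.output_dir``: the phantom volume and truth
    mask (MetaImage), the coarse mask, the ring table (YAML), the
    initialization and final meshes (PLY), the metrics report (JSON) and the
    manifest (JSON, with a SHA-256 per artifact).  Identical config + seed
    give an identical report (and identical artifact hashes in
    single-threaded mode).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    report: dict = {"stages": {}}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - stage boundary
                raise PipelineError(name, e) from e
            report["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
            return result

        return deco

    # --- phantom ----------------------------------------------------------
    @stage("phantom")
    def _phantom():
        spec = PhantomSpec(**{**asdict(cfg.phantom), "seed": cfg.seed})
        vol, mask, gt_mesh = generate_phantom(spec, cfg.points_per_ring)
        artifacts["volume"] = write_volume(vol, out / "volume.mhd")
        artifacts["truth_mask"] = write_mask(mask, out / "truth_mask.mhd")
        artifacts["truth_mesh"] = gt_mesh.save_ply(out / "truth_mesh.ply")
        return spec, vol, mask, gt_mesh

    spec, vol, mask, gt_mesh = _phantom

    # --- coarse -----------------------------------------------------------
    @stage("coarse")
    def _coarse():
        if cfg.coarse_mode == "degraded-truth":
            coarse = degrade_mask(mask, seed=cfg.seed, **cfg.degrade_kwargs)
        else:
            stack = slice_volume(vol, mask, "train")
            model = build_network(cfg.net, seed=cfg.seed)
            tc = TrainConfig(**{**asdict(cfg.train), "seed": cfg.seed})
            log = train(model, stack, tc)
            log.to_csv(out / "train_log.csv")
            artifacts["train_log"] = out / "train_log.csv"
            model.save_npz(out / "model.npz")
            artifacts["model"] = out / "model.npz"
            pred = predict_stack(model, stack)
            _, coarse = restack(pred)
        artifacts["coarse_mask"] = write_mask(coarse, out / "coarse_mask.mhd")
        return coarse

    coarse = _coarse

    # --- initialize ---------------------------------------------------------
    @stage("initialize")
    def _init():
        mesh, rings = initialize_mesh(coarse, k=cfg.k, points_per_ring=cfg.points_per_ring)
        artifacts["ring_table"] = rings_to_yaml(rings, out / "rings.yaml")
        artifacts["init_mesh"] = mesh.save_ply(out / "init_mesh.ply")
        return mesh

    init_mesh = _init

    # --- refine -------------------------------------------------------------
    @stage("refine")
    def _refine():
        res = evolve(init_mesh, vol, cfg.snake)
        artifacts["final_mesh"] = res.mesh.save_ply(out / "final_mesh.ply")
        energy_csv = out / "energy_log.csv"
        lines = ["iteration,e_internal_1,e_internal_2,e_external,e_init,total"]
        lines += [
            f"{i},{b.e_internal_1:.8g},{b.e_internal_2:.8g},{b.e_external:.8g},"
            f"{b.e_init:.8g},{b.total:.8g}"
            for i, b in enumerate(res.history)
        ]
        energy_csv.write_text("\n".join(lines) + "\n")
        artifacts["energy_log"] = energy_csv
        return res

    refine_res = _refine

    # --- evaluate -----------------------------------------------------------
    @stage("evaluate")
    def _eval():
        pred_pts = sample_surface(refine_res.mesh, cfg.surface_samples, seed=cfg.seed)
        true_pts = sample_surface(gt_mesh, cfg.surface_samples, seed=cfg.seed)
        pair = SurfacePair(pred_pts, true_pts)
        cc = confusion_counts(coarse.data, mask.data)
        acc, macc, miou = pixel_metrics(cc)
        zb = spec.base_z
        return {
            "mean_surface_distance_mm": mean_surface_distance(pair),
            "hausdorff_distance_mm": hausdorff_distance(pair),
            "modified_dice_coarse": modified_dice(coarse, mask),
            "coarse_pixel_acc": acc,
            "coarse_mean_acc": macc,
            "coarse_mean_iou": miou,
            "truth_volume_ml": mask.foreground_volume_ml(),
            "leaked_vertices": leak_test(refine_res.mesh, zb, spec.spacing[2]),
            "snake_iterations": refine_res.iterations,
            "snake_converged": refine_res.converged,
        }

    report["metrics"] = _eval
    (out / "metrics.json").write_text(json.dumps(report["metrics"], indent=2, default=float))
    artifacts["metrics"] = out / "metrics.json"

    report["manifest"] = {
        name: {"path": str(p), "sha256": _sha256(Path(p))} for name, p in artifacts.items()
    }
    (out / "manifest.json").write_text(json.dumps(report["manifest"], indent=2))
    return report
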