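"""End-to-end pipeline: simulate -> synthesize training set -> train ->
predict -> extract -> assess, driven by one config and one seed.

The global seed is fanned out to per-stage seeds through a fixed
:class:`numpy.random.SeedSequence` derivation, so each stage is independently
reproducible and no two stages share a stream. Every run writes its artifacts
plus a JSON report containing all computed metrics and the SHA-256 hash of
the canonicalized config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import assess, dense_net, simulator, training_synth
from .io_formats import CameraModel, export_patchset, write_locs, write_movie

logger = logging.getLogger("paintdense")

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]

STAGES = ("simulate", "make_training", "train", "predict", "extract", "assess")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    The simulate section sets the field, sparse/high-density regimes and
    camera; training wraps the summing and network configs; extract and
    assess carry their stage parameters. All module-level invariants apply.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0

    # --- simulate ---
    frame_shape: tuple[int, int] = (64, 64)
    structures: simulator.StructureSpec = field(
        default_factory=lambda: simulator.StructureSpec(
            n_filaments=3, n_patches=2, n_outlines=3,
            filament_site_density_per_um=300.0,
            patch_site_density_per_um2=3000.0,
            outline_site_density_per_um=300.0))
    kinetics: simulator.KineticsConfig = field(default_factory=simulator.KineticsConfig)
    camera: CameraModel = field(default_factory=CameraModel)
    integration_time: float = 0.15
    sparse_density: float = 0.028   # emitters/µm², training acquisition
    predict_density: float = 1.5    # emitters/µm², high-density acquisition
    n_sparse_frames: int = 1200
    n_predict_frames: int = 150

    # --- training ---
    summing: training_synth.SummingConfig = field(
        default_factory=lambda: training_synth.SummingConfig(
            patch_size=16, target_density=1.9, n_outputs=2000))
    map_cfg: dense_net.TargetMapConfig = field(
        default_factory=lambda: dense_net.TargetMapConfig(upsampling=4))
    train_cfg: dense_net.TrainConfig = field(
        default_factory=lambda: dense_net.REDUCED_TRAIN_CONFIG)

    # --- extract / assess ---
    extraction: dense_net.ExtractionConfig = field(
        default_factory=dense_net.ExtractionConfig)
    match_radius_px: float = 1.0
    nena_cutoff_nm: float = 100.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("structures", simulator.StructureSpec),
                         ("kinetics", simulator.KineticsConfig),
                         ("camera", CameraModel),
                         ("summing", training_synth.SummingConfig),
                         ("map_cfg", dense_net.TargetMapConfig),
                         ("train_cfg", dense_net.TrainConfig),
                         ("extraction", dense_net.ExtractionConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "frame_shape" in d:
            d["frame_shape"] = tuple(d["frame_shape"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("pipeline config must be a YAML mapping")
        return cls.from_dict(raw)


def _config_hash(cfg: PipelineConfig) -> str:
    d = cfg.to_dict()
    d.pop("out_dir", None)  # where artifacts land does not change the run
    canon = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % 2**31)
            for name, c in zip(STAGES, children)}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow; return (and write) the JSON report.

    Any stage failure raises :class:`StageError` naming the stage; artifacts
    written by earlier stages are preserved in ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    report: dict = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                    "stage_seeds": seeds, "metrics": {}, "artifacts": {}}
    met = report["metrics"]
    t0 = time.time()

    stage = "simulate"
    try:
        H, W = cfg.frame_shape
        px = cfg.camera.pixel_size
        field_nm = (W * px, H * px)
        emitters = simulator.place_structures(cfg.structures, field_nm,
                                              seed=seeds[stage])
        if emitters.n_sites == 0:
            raise ValueError("structure spec produced an empty field")
        kin = cfg.kinetics
        c_sparse = simulator.concentration_for_density(emitters, kin, cfg.sparse_density)
        kin_sparse = dataclasses.replace(kin, concentration=c_sparse)
        sparse_movie, sparse_truth = simulator.simulate_movie(
            emitters, kin_sparse, cfg.camera, cfg.frame_shape,
            cfg.n_sparse_frames, cfg.integration_time, seed=seeds[stage])
        write_movie(sparse_movie, out / "sparse_movie.tif")
        write_locs(sparse_truth, out / "sparse_truth.hdf5", pixel_size=px,
                   shape=cfg.frame_shape)
        met["n_sites"] = emitters.n_sites
        met["sparse_concentration_M"] = c_sparse
        met["sparse_density_measured"] = simulator.measured_density(
            sparse_truth, kin_sparse, emitters.area_um2, cfg.n_sparse_frames)
        met["sparse_density_expected"] = simulator.expected_density(emitters, kin_sparse)
        report["artifacts"]["sparse_movie"] = str(out / "sparse_movie.tif")
    except Exception as e:  # noqa: BLE001 - abort with stage name
        raise StageError(stage, e) from e

    stage = "make_training"
    try:
        scfg = dataclasses.replace(cfg.summing, seed=seeds[stage])
        sparse_ps = training_synth.extract_sparse_patches(sparse_movie, sparse_truth, scfg)
        if len(sparse_ps) == 0:
            raise ValueError("no sparse patches extracted")
        offset = cfg.camera.offset
        if scfg.target_density is not None:
            k = training_synth.choose_k_for_density(
                scfg.target_density, sparse_ps.mean_emitters_per_patch,
                scfg.patch_size, px)
            scfg = dataclasses.replace(scfg, k_per_output=k)
        summed = training_synth.sum_patches(sparse_ps, scfg, offset)
        export_patchset(summed, out / "training_patches.tif")
        met["n_sparse_patches"] = len(sparse_ps)
        met["k_per_output"] = scfg.k_per_output
        met["training_density"] = summed.density_per_um2()
        met["training_density_target"] = scfg.target_density
        report["artifacts"]["training_patches"] = str(out / "training_patches.tif")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "train"
    try:
        tcfg = dataclasses.replace(cfg.train_cfg, seed=seeds[stage])
        model = dense_net.train_model(summed, tcfg, cfg.map_cfg)
        model.save(out / "model")
        met["final_train_loss"] = model.history[-1][1]
        met["final_val_loss"] = model.history[-1][2]
        report["artifacts"]["model"] = str(out / "model.npz")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "predict"
    try:
        c_hd = simulator.concentration_for_density(emitters, kin, cfg.predict_density)
        kin_hd = dataclasses.replace(kin, concentration=c_hd)
        hd_movie, hd_truth = simulator.simulate_movie(
            emitters, kin_hd, cfg.camera, cfg.frame_shape,
            cfg.n_predict_frames, cfg.integration_time, seed=seeds[stage])
        write_movie(hd_movie, out / "hd_movie.tif")
        write_locs(hd_truth, out / "hd_truth.hdf5", pixel_size=px, shape=cfg.frame_shape)
        pred = dense_net.predict(model, hd_movie)
        met["hd_density_measured"] = simulator.measured_density(
            hd_truth, kin_hd, emitters.area_um2, cfg.n_predict_frames)
        met["n_predict_frames"] = pred.n_frames
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "extract"
    try:
        locs = dense_net.extract_localizations(pred, cfg.extraction,
                                               target_count=len(hd_truth))
        write_locs(locs, out / "predicted_locs.hdf5", pixel_size=px,
                   shape=cfg.frame_shape)
        met["n_extracted"] = len(locs)
        report["artifacts"]["predicted_locs"] = str(out / "predicted_locs.hdf5")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "assess"
    try:
        m = assess.match_localizations(hd_truth, locs, cfg.match_radius_px)
        met.update({f"match_{k}": v for k, v in m.items()})
        met["acquisition_time_gt_s"] = assess.acquisition_time(
            cfg.n_sparse_frames, cfg.integration_time)
        met["acquisition_time_hd_s"] = assess.acquisition_time(
            cfg.n_predict_frames, cfg.integration_time)
        try:
            sigma, diag = assess.nena_precision(locs, px, cfg.nena_cutoff_nm)
            met["nena_sigma_nm"] = sigma
            met["nena_n_pairs"] = diag["n_pairs"]
        except ValueError as ve:
            met["nena_sigma_nm"] = None
            logger.warning("NeNA skipped: %s", ve)
        rc = assess.RenderConfig(oversampling=cfg.map_cfg.upsampling)
        img_gt = assess.render_image(hd_truth, cfg.frame_shape, rc)
        img_pred = assess.render_image(locs, cfg.frame_shape, rc)
        met["normalized_pcc"] = assess.normalized_pcc(img_gt, img_pred)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    report["runtime_s"] = time.time() - t0
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    logger.info("pipeline finished in %.1f s; report at %s",
                report["runtime_s"], out / "report.json")
    return report
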