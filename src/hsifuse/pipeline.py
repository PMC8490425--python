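"""End-to-end orchestration: calibrate -> smooth -> trim -> upsample ->
register -> crop ROI -> fuse -> (optionally) evaluate.

A :class:`PipelineConfig` declares every stage parameter and every seed
explicitly and round-trips losslessly through YAML, so a run is
reproducible from its manifest alone.  Each stage logs its similarity
metrics (SSIM / MI / PCC before and after registration) and the manifest
records the config hash, per-stage metrics and output artifact paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import synthetic_scenes as scenes
from .core_data import (CalibrationRefs, HSCube, calibrate, crop_bands, pseudo_rgb,
                        read_envi, smooth_spectra, to_grayscale, write_envi)
from .registration import (METRICS, RegistrationError, TransformModel,
                           coarse_to_fine_band_search, crop_common_roi,
                           register_features, register_intensity, warp)
from .spectral_fusion import (find_cutoffs, fixed_cutoffs, fuse, relative_difference,
                              transfer_labels, upsample_bilinear)

logger = logging.getLogger("hsifuse")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    # input: either a synthetic scene spec ...
    scene_kind: str | None = "plastic"     # reference_panel|registration_target|plastic
    scene_seed: int = 0
    vnir_dims: tuple[int, int] = (96, 96)
    nir_dims: tuple[int, int] = (48, 48)
    vnir_bands: int = 120
    nir_bands: int = 60
    # ... or ENVI paths (scene_kind=None)
    vnir_path: str | None = None
    nir_path: str | None = None

    # pre-processing
    smoothing_window: int = 5
    clip_max: float = 2.0

    # registration
    technique: str = "feature"             # feature|intensity|true
    detector: str = "blob"
    transform_kind: str = "projective"
    registration_seed: int = 0
    msac_trials: int = 1000

    # band search
    band_search: bool = False
    band_search_steps: tuple[int, int] = (7, 3)
    band_search_metric: str = "ssim"

    # fusion
    cutoff_mode: str = "auto"              # auto (from repeats) | fixed
    vnir_cut_nm: tuple[float, float] = (435.0, 901.0)
    nir_cut_nm: tuple[float, float] = (956.0, 1638.0)
    k_bands: int = 5
    run_length: int = 5

    # evaluation
    evaluate: bool = False
    eval_method: str = "svm"
    eval_seeds: tuple[int, ...] = (0,)

    output_dir: str = "hsifuse_out"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("vnir_dims", "nir_dims", "band_search_steps", "vnir_cut_nm",
                    "nir_cut_nm", "eval_seeds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _make_scene(cfg: PipelineConfig) -> scenes.ScenePair:
    spec = scenes.SceneSpec(
        vnir_grid=np.linspace(400.0, 1000.0, cfg.vnir_bands),
        nir_grid=np.linspace(900.0, 1700.0, cfg.nir_bands),
        vnir_dims=tuple(cfg.vnir_dims), nir_dims=tuple(cfg.nir_dims),
        seed=cfg.scene_seed)
    maker = {"reference_panel": scenes.make_reference_panel,
             "registration_target": scenes.make_registration_target,
             "plastic": scenes.make_plastic_scene}
    if cfg.scene_kind not in maker:
        raise ValueError(f"unknown scene kind {cfg.scene_kind!r}")
    return maker[cfg.scene_kind](spec)


def _gray(cube: HSCube) -> np.ndarray:
    return to_grayscale(pseudo_rgb(cube))


def _metrics(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    out = {}
    for name, fn in METRICS.items():
        try:
            out[name] = float(fn(a, b))
        except ValueError:
            out[name] = float("nan")
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full framework; returns the manifest dict.

    Any stage failure raises :class:`StageError` naming the stage; partial
    artifacts written before the failure are preserved in the output dir.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.hash(),
                      "config": dataclasses.asdict(cfg), "stages": {}}

    # --- acquire -------------------------------------------------------
    try:
        if cfg.scene_kind is not None:
            scene = _make_scene(cfg)
            vnir, nir = scene.vnir, scene.nir
        else:
            scene = None
            vnir = read_envi(cfg.vnir_path)
            nir = read_envi(cfg.nir_path)
    except Exception as e:
        raise StageError("acquire", e)
    manifest["stages"]["acquire"] = {"vnir_shape": list(vnir.shape),
                                     "nir_shape": list(nir.shape)}

    # --- pre-process ---------------------------------------------------
    try:
        vnir = smooth_spectra(vnir, cfg.smoothing_window)
        nir = smooth_spectra(nir, cfg.smoothing_window)
    except Exception as e:
        raise StageError("preprocess", e)
    manifest["stages"]["preprocess"] = {"smoothing_window": cfg.smoothing_window}

    # --- operating bandwidth ------------------------------------------
    try:
        if cfg.cutoff_mode == "auto" and scene is not None and scene.repeats:
            v_cut = find_cutoffs(relative_difference(scene.vnir, scene.repeats["vnir"]),
                                 cfg.run_length)
            n_cut = find_cutoffs(relative_difference(scene.nir, scene.repeats["nir"]),
                                 cfg.run_length)
        else:
            v_cut = fixed_cutoffs(vnir, *cfg.vnir_cut_nm)
            n_cut = fixed_cutoffs(nir, *cfg.nir_cut_nm)
        vnir_t = crop_bands(vnir, v_cut.initial_nm, v_cut.final_nm)
        nir_t = crop_bands(nir, n_cut.initial_nm, n_cut.final_nm)
    except Exception as e:
        raise StageError("bandwidth", e)
    manifest["stages"]["bandwidth"] = {
        "vnir_cut_nm": [v_cut.initial_nm, v_cut.final_nm],
        "nir_cut_nm": [n_cut.initial_nm, n_cut.final_nm],
        "vnir_bands": vnir_t.n_bands, "nir_bands": nir_t.n_bands}

    # --- upsample ------------------------------------------------------
    try:
        nir_up = upsample_bilinear(nir_t, vnir_t.shape[:2])
    except Exception as e:
        raise StageError("upsample", e)
    manifest["stages"]["upsample"] = {"target_dims": list(vnir_t.shape[:2])}

    # --- register ------------------------------------------------------
    try:
        f_gray, m_gray = _gray(vnir_t), _gray(nir_up)
        before = _metrics(f_gray, m_gray)
        if cfg.band_search:
            search = coarse_to_fine_band_search(
                vnir_t, nir_up, cfg.band_search_steps, cfg.band_search_metric,
                seed=cfg.registration_seed, detector=cfg.detector,
                kind=cfg.transform_kind, trials=min(cfg.msac_trials, 200))
            bi, bj = search.best_pair
            f_gray = vnir_t.data[:, :, bi]
            m_gray = nir_up.data[:, :, bj]
            manifest["stages"]["band_search"] = {
                "best_pair": [int(bi), int(bj)], "best_score": search.best_score}
        if cfg.technique == "feature":
            t = register_features(f_gray, m_gray, detector=cfg.detector,
                                  kind=cfg.transform_kind, seed=cfg.registration_seed,
                                  trials=cfg.msac_trials)
        elif cfg.technique == "intensity":
            t = register_intensity(f_gray, m_gray, kind=cfg.transform_kind)
        elif cfg.technique == "true" and scene is not None:
            # the generator's truth composed with the upsampling scaling
            nr, nc = nir_t.shape[:2]
            vr, vc = vnir_t.shape[:2]
            down = np.diag([(nc - 1) / (vc - 1), (nr - 1) / (vr - 1), 1.0])
            t = TransformModel(scene.true_transform.kind,
                               scene.true_transform.matrix @ down,
                               {"technique": "true"})
        else:
            raise ValueError(f"unknown technique {cfg.technique!r}")
        nir_reg, mask = warp(nir_up, t, vnir_t.shape[:2])
        vnir_roi, nir_roi = crop_common_roi(vnir_t, nir_reg, mask)
        after = _metrics(_gray(vnir_roi), _gray(nir_roi))
        t.to_json(out / "transform.json")
    except (RegistrationError, ValueError) as e:
        raise StageError("register", e)
    manifest["stages"]["register"] = {
        "technique": cfg.technique, "kind": cfg.transform_kind,
        "metrics_before": before, "metrics_after": after,
        "roi": [int(x) for x in vnir_roi.meta["roi"]]}
    logger.info("register: SSIM %.3f -> %.3f", before["ssim"], after["ssim"])

    # --- fuse ----------------------------------------------------------
    try:
        fv = fixed_cutoffs(vnir_roi, vnir_roi.wavelengths[0], vnir_roi.wavelengths[-1])
        fn = fixed_cutoffs(nir_roi, nir_roi.wavelengths[0], nir_roi.wavelengths[-1])
        fused = fuse(vnir_roi, nir_roi, fv, fn, k_bands=cfg.k_bands)
        fused.write(out / "fused.raw")
        write_envi(vnir_roi, out / "vnir_roi.raw")
        write_envi(nir_roi, out / "nir_roi.raw")
    except Exception as e:
        raise StageError("fuse", e)
    manifest["stages"]["fuse"] = {
        "band_count": fused.cube.n_bands,
        "segment_boundary": fused.segment_boundary,
        "gap_nm": [float(g) for g in fused.gap_nm],
        "mean_offset": fused.offset_applied}

    # --- evaluate ------------------------------------------------------
    if cfg.evaluate and scene is not None and scene.color_gt is not None:
        from .evaluation import compare_modalities
        try:
            report = compare_modalities(scene, method=cfg.eval_method,
                                        seeds=cfg.eval_seeds)
            manifest["stages"]["evaluate"] = {
                "means": {p: report.means[p] for p in report.means},
                "p_values": {f"{p}:{a}>{b}": v
                             for (p, a, b), v in report.p_values.items()}}
            report.to_frame().to_csv(out / "evaluation.csv", index=False)
        except Exception as e:
            raise StageError("evaluate", e)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if scene is not None and scene.vnir_labels is not None:
        transferred = transfer_labels(scene.vnir_labels, vnir_t.shape[:2])
        manifest["stages"]["labels"] = {"n_classes": transferred.n_classes}
    return manifest


def simulate(kind: str, seed: int, out_dir: str | Path, n_scenes: int = 1,
             vnir_dims: tuple[int, int] = (96, 96),
             nir_dims: tuple[int, int] = (48, 48)) -> list[Path]:
    """Generate synthetic scene fixtures on disk with their manifests."""
    maker = {"reference_panel": scenes.make_reference_panel,
             "registration_target": scenes.make_registration_target,
             "plastic": scenes.make_plastic_scene}
    if kind not in maker:
        raise ValueError(f"unknown scene kind {kind!r}")
    written = []
    for i in range(n_scenes):
        spec = scenes.SceneSpec(vnir_dims=vnir_dims, nir_dims=nir_dims, seed=seed + i)
        pair = maker[kind](spec)
        dest = Path(out_dir) / f"{kind}_{seed + i:04d}"
        pair.write(dest)
        written.append(dest)
    return written
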