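"""Synthetic dual-camera scene generation.

The real VNIR/NIR captures this toolkit targets (registration targets,
flat reference panels, colored-plastic scenes, in-vivo tissue) are not
redistributable, so every downstream stage is exercised on synthetic
scene pairs with *known* geometry, *known* spectral structure and a
band-dependent sensor-noise model:

* :func:`make_reference_panel` — a spatially uniform, spectrally flat
  panel captured twice through the noise model, for the relative-
  difference bandwidth analysis (the injected noisy-edge band indices are
  recorded as ground truth);
* :func:`make_registration_target` — a high-contrast blob/checkerboard
  pattern rendered in the VNIR frame and re-rendered through a known
  projective misalignment in the NIR frame;
* :func:`make_plastic_scene` — shaped regions whose "color" spectral
  structure lives below 900 nm and whose "material" absorption features
  live above 956 nm, so the color problem is VNIR-resolvable, the
  material problem NIR-resolvable, and the joint material-color problem
  requires both ranges.

Every generator is a pure function of (spec, seed): identical inputs give
bit-identical outputs.  The noise model is heteroscedastic Gaussian with a
"bathtub" std profile — elevated near each camera's spectral extremes —
which reproduces the shape of real push-broom sensor noise without
claiming the sensors are Gaussian.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .core_data import HSCube, LabelMap, write_envi, write_labelmap
from .registration import TransformModel

NoiseProfile = Callable[[np.ndarray], np.ndarray]


def bathtub_noise(base_std: float = 0.01, edge_factor: float = 10.0,
                  edge_fraction: float = 0.1) -> NoiseProfile:
    """Per-band noise std profile: ``base_std`` in the interior, scaled by
    ``edge_factor`` over the first and last ``edge_fraction`` of the grid."""
    def profile(wavelengths: np.ndarray) -> np.ndarray:
        n = len(wavelengths)
        k = int(math.ceil(edge_fraction * n))
        std = np.full(n, base_std, dtype=float)
        if k > 0:
            std[:k] *= edge_factor
            std[n - k:] *= edge_factor
        return std
    return profile


def zero_noise() -> NoiseProfile:
    return lambda wavelengths: np.zeros(len(wavelengths))


def random_projective(seed: int, max_rotation_deg: float = 5.0,
                      scale_range: tuple[float, float] = (0.9, 1.1),
                      max_translation_px: float = 6.0,
                      max_tilt: float = 0.001) -> TransformModel:
    """A random projective transform sampled as a perturbation of identity,
    matching a near-perpendicular two-camera rig: rotation <= 5 degrees,
    scale 0.9-1.1, small translation, tilt <= 0.001."""
    rng = np.random.default_rng(seed)
    rot = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))
    s = rng.uniform(*scale_range)
    tx, ty = rng.uniform(-max_translation_px, max_translation_px, size=2)
    g, h = rng.uniform(-max_tilt, max_tilt, size=2)
    c, sn = np.cos(rot), np.sin(rot)
    m = np.array([[s * c, -s * sn, tx],
                  [s * sn, s * c, ty],
                  [g, h, 1.0]])
    return TransformModel("projective", m, {"technique": "synthetic_truth", "seed": seed})


@dataclass
class SceneSpec:
    """Parameters of a synthetic dual-camera capture.

    Defaults are desk-scale (seconds per scene): 120 VNIR bands over
    400-1000 nm, 60 NIR bands over 900-1700 nm, 96x96 / 48x48 pixels.
    :meth:`full_scale` gives the real-rig geometry (826/172 bands,
    939x743 / 320x253 pixels).
    """

    vnir_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(400.0, 1000.0, 120))
    nir_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(900.0, 1700.0, 60))
    vnir_dims: tuple[int, int] = (96, 96)
    nir_dims: tuple[int, int] = (48, 48)
    true_transform: TransformModel | None = None
    noise_profile: NoiseProfile | None = None   # None -> bathtub defaults
    base_noise_std: float = 0.01
    edge_noise_factor: float = 10.0
    edge_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.vnir_grid = np.asarray(self.vnir_grid, dtype=float)
        self.nir_grid = np.asarray(self.nir_grid, dtype=float)
        for g in (self.vnir_grid, self.nir_grid):
            if np.any(np.diff(g) <= 0):
                raise ValueError("wavelength grids must be strictly increasing")
        for d in (self.vnir_dims, self.nir_dims):
            if d[0] < 8 or d[1] < 8:
                raise ValueError("scene dims must be at least 8x8")
        if self.base_noise_std < 0:
            raise ValueError("noise std must be >= 0")

    @classmethod
    def full_scale(cls, **kw) -> "SceneSpec":
        kw.setdefault("vnir_grid", np.linspace(400.0, 1000.0, 826))
        kw.setdefault("nir_grid", np.linspace(900.0, 1700.0, 172))
        kw.setdefault("vnir_dims", (939, 743))
        kw.setdefault("nir_dims", (320, 253))
        return cls(**kw)

    def noise(self) -> NoiseProfile:
        if self.noise_profile is not None:
            return self.noise_profile
        return bathtub_noise(self.base_noise_std, self.edge_noise_factor,
                             self.edge_fraction)


@dataclass
class ScenePair:
    """A synthetic VNIR+NIR capture with ground truth."""

    vnir: HSCube
    nir: HSCube
    vnir_labels: LabelMap
    true_transform: TransformModel
    repeats: dict[str, HSCube] | None = None
    color_gt: LabelMap | None = None
    material_gt: LabelMap | None = None
    material_color_gt: LabelMap | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vdims = self.vnir.shape[:2]
        for lm in (self.vnir_labels, self.color_gt, self.material_gt,
                   self.material_color_gt):
            if lm is not None and lm.labels.shape != vdims:
                raise ValueError("label maps must match VNIR spatial dims")
        if self.repeats:
            for key, cube in self.repeats.items():
                primary = self.vnir if key == "vnir" else self.nir
                if cube.shape != primary.shape:
                    raise ValueError("repeat captures must share dims with primaries")

    def write(self, out_dir: str | Path) -> None:
        """Write ENVI cubes, PNG/JSON labels and a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_envi(self.vnir, out / "vnir.raw")
        write_envi(self.nir, out / "nir.raw")
        write_labelmap(self.vnir_labels, out / "vnir_labels.png")
        if self.repeats:
            for key, cube in self.repeats.items():
                write_envi(cube, out / f"{key}_repeat.raw")
        for name, lm in (("color_gt", self.color_gt), ("material_gt", self.material_gt),
                         ("material_color_gt", self.material_color_gt)):
            if lm is not None:
                write_labelmap(lm, out / f"{name}.png")
        manifest = {
            "true_transform": self.true_transform.matrix.tolist(),
            "transform_kind": self.true_transform.kind,
            "meta": {k: v for k, v in self.meta.items()
                     if isinstance(v, (int, float, str, list, dict, bool))},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed & 0x7FFFFFFF, stream]))


def sensor_capture(ideal: HSCube, noise_profile: NoiseProfile,
                   seed: int | np.random.Generator) -> HSCube:
    """Pass an ideal cube through the sensor model: independent zero-mean
    Gaussian noise with per-band std from the profile, clipped at 0."""
    std = np.asarray(noise_profile(ideal.wavelengths), dtype=float)
    if std.shape != (ideal.n_bands,):
        raise ValueError("noise profile must give one std per band")
    if np.any(std < 0):
        raise ValueError("noise std must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = ideal.data + rng.standard_normal(ideal.shape) * std[None, None, :]
    meta = dict(ideal.meta)
    meta["sensor_noise"] = True
    return HSCube(np.clip(noisy, 0.0, None), ideal.wavelengths.copy(), ideal.modality, meta)


def _true_cutoff_indices(std: np.ndarray) -> tuple[int, int]:
    """First/last band whose injected noise is at the interior (clean) level."""
    interior = std.min()
    clean = np.flatnonzero(std <= interior * 1.5 + 1e-30)
    return int(clean[0]), int(clean[-1])


# ---------------------------------------------------------------------------
# Reference panel (flat-reflectance standard, captured twice)
# ---------------------------------------------------------------------------

def make_reference_panel(spec: SceneSpec, reflectance: float = 0.95) -> ScenePair:
    """A spatially uniform, spectrally flat panel captured twice per camera.

    Emulates a certified reflectance standard: the true reflectance is
    ``reflectance`` at every pixel and wavelength, and the only structure
    in the captures is the band-dependent sensor noise.  The band indices
    where the injected noise first drops to the interior level are stored
    in ``meta['true_cutoffs']`` so bandwidth-recovery can be scored.
    """
    noise = spec.noise()
    cubes: dict[str, HSCube] = {}
    repeats: dict[str, HSCube] = {}
    cutoffs: dict[str, tuple[int, int]] = {}
    for stream, (name, grid, dims, modality) in enumerate([
            ("vnir", spec.vnir_grid, spec.vnir_dims, "VNIR"),
            ("nir", spec.nir_grid, spec.nir_dims, "NIR")]):
        ideal = HSCube(np.full(dims + (len(grid),), reflectance), grid.copy(), modality,
                       {"scene": "reference_panel"})
        cubes[name] = sensor_capture(ideal, noise, _rng(spec.seed, 10 + stream))
        repeats[name] = sensor_capture(ideal, noise, _rng(spec.seed, 20 + stream))
        cutoffs[name] = _true_cutoff_indices(noise(grid))
    labels = LabelMap(np.ones(spec.vnir_dims, dtype=np.int64), ["panel"])
    pair = ScenePair(cubes["vnir"], cubes["nir"], labels,
                     TransformModel.identity("projective"), repeats=repeats,
                     meta={"scene": "reference_panel", "true_reflectance": reflectance,
                           "true_cutoffs": cutoffs, "seed": spec.seed})
    return pair


# ---------------------------------------------------------------------------
# Registration target
# ---------------------------------------------------------------------------

def _pattern_fn(spec: SceneSpec, rng: np.random.Generator):
    """Analytic high-contrast pattern in VNIR-frame coordinates: a soft
    checkerboard plus random Gaussian blobs.  Returns (fn, blob_centers)."""
    rows, cols = spec.vnir_dims
    period = max(8.0, min(rows, cols) / 6.0)
    n_blobs = max(12, (rows * cols) // 700)
    centers = np.column_stack([rng.uniform(4, cols - 4, n_blobs),
                               rng.uniform(4, rows - 4, n_blobs)])
    sigmas = rng.uniform(1.5, 4.0, n_blobs)
    signs = rng.choice([-1.0, 1.0], n_blobs)

    def fn(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        checker = 0.25 * (np.sin(2 * np.pi * x / period) *
                          np.sin(2 * np.pi * y / period))
        out = 0.5 + checker
        for (cx, cy), s, sg in zip(centers, sigmas, signs):
            out = out + 0.45 * sg * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * s ** 2))
        return np.clip(out, 0.0, 1.0)

    return fn, centers


def _smooth_signature(grid: np.ndarray, rng: np.random.Generator,
                      lo: float = 0.2, hi: float = 0.9) -> np.ndarray:
    """A random smooth reflectance profile over the grid (3 cosine modes)."""
    span = grid[-1] - grid[0]
    u = (grid - grid[0]) / span
    sig = np.zeros_like(grid)
    for k in range(1, 4):
        sig = sig + rng.uniform(-1, 1) * np.cos(np.pi * k * u + rng.uniform(0, np.pi))
    sig = (sig - sig.min()) / (sig.max() - sig.min() + 1e-12)
    return lo + (hi - lo) * sig


def make_registration_target(spec: SceneSpec) -> ScenePair:
    """Geometric registration target under a known projective misalignment.

    The pattern lives in the VNIR frame; the NIR cube samples the same
    pattern at ``true_transform(nir_pixel)`` so the stored transform maps
    NIR (moving) coordinates exactly onto VNIR (fixed) coordinates.
    Foreground/background carry distinct smooth spectral signatures
    spanning both camera ranges; blob centers are stored as control
    points in both frames.
    """
    rng = _rng(spec.seed, 1)
    true_t = spec.true_transform or random_projective(spec.seed ^ 0x5EED)
    fn, centers = _pattern_fn(spec, rng)
    vr, vc = spec.vnir_dims
    nr, nc = spec.nir_dims
    yy, xx = np.mgrid[0:vr, 0:vc]
    vnir_pattern = fn(xx.astype(float), yy.astype(float))
    nyy, nxx = np.mgrid[0:nr, 0:nc]
    nir_pts = np.column_stack([nxx.ravel(), nyy.ravel()]).astype(float)
    mapped = true_t.apply(nir_pts)          # NIR pixel -> VNIR-frame coords
    nir_pattern = fn(mapped[:, 0], mapped[:, 1]).reshape(nr, nc)
    inside = ((mapped[:, 0] >= 0) & (mapped[:, 0] < vc) &
              (mapped[:, 1] >= 0) & (mapped[:, 1] < vr))
    if inside.mean() < 0.05 or nir_pattern.std() < 1e-3:
        raise ValueError("true_transform maps the pattern outside the NIR frame")

    sig_rng = _rng(spec.seed, 2)
    full_grid = np.concatenate([spec.vnir_grid, spec.nir_grid])
    bg_full = _smooth_signature(full_grid, sig_rng, 0.15, 0.45)
    fg_full = _smooth_signature(full_grid, sig_rng, 0.55, 0.95)
    nv = len(spec.vnir_grid)
    noise = spec.noise()
    cubes = {}
    for name, pattern, grid, bg, fg, modality, stream in [
            ("vnir", vnir_pattern, spec.vnir_grid, bg_full[:nv], fg_full[:nv], "VNIR", 11),
            ("nir", nir_pattern, spec.nir_grid, bg_full[nv:], fg_full[nv:], "NIR", 12)]:
        ideal = bg[None, None, :] + pattern[:, :, None] * (fg - bg)[None, None, :]
        cube = HSCube(ideal, grid.copy(), modality, {"scene": "registration_target"})
        cubes[name] = sensor_capture(cube, noise, _rng(spec.seed, stream))
    labels = LabelMap((vnir_pattern > 0.5).astype(np.int64) + 1,
                      ["background", "foreground"])
    inv = true_t.inverse()
    ctrl_nir = inv.apply(centers)
    keep = ((ctrl_nir[:, 0] >= 2) & (ctrl_nir[:, 0] < nc - 2) &
            (ctrl_nir[:, 1] >= 2) & (ctrl_nir[:, 1] < nr - 2))
    return ScenePair(cubes["vnir"], cubes["nir"], labels, true_t,
                     meta={"scene": "registration_target", "seed": spec.seed,
                           "control_points_vnir": centers[keep],
                           "control_points_nir": ctrl_nir[keep]})


# ---------------------------------------------------------------------------
# Plastic-like material/color scene
# ---------------------------------------------------------------------------

#: "color" structure is confined below this wavelength (nm)
COLOR_MAX_NM = 900.0
#: "material" absorption features are confined above this wavelength (nm)
MATERIAL_MIN_NM = 956.0


def _color_component(grid: np.ndarray, color_idx: int, n_colors: int) -> np.ndarray:
    """Distinct reflectance profile for a color, zero at and above 900 nm."""
    comp = np.zeros_like(grid)
    vis = grid < COLOR_MAX_NM
    if not np.any(vis):
        return comp
    lam = grid[vis]
    center = 430.0 + (COLOR_MAX_NM - 520.0) * (color_idx + 0.5) / n_colors
    comp[vis] = 0.35 * np.exp(-((lam - center) / 60.0) ** 2)
    comp[vis] += 0.10 * np.cos(2 * np.pi * (color_idx + 1) * (lam - 400.0) / 500.0)
    return comp


def _material_component(grid: np.ndarray, mat_idx: int, n_mats: int) -> np.ndarray:
    """Distinct absorption features for a material, zero below 956 nm."""
    comp = np.zeros_like(grid)
    nir = grid > MATERIAL_MIN_NM
    if not np.any(nir):
        return comp
    lam = grid[nir]
    top = grid[-1]
    center = MATERIAL_MIN_NM + 80.0 + (top - MATERIAL_MIN_NM - 160.0) * \
        (mat_idx + 0.5) / n_mats
    comp[nir] = -0.30 * np.exp(-((lam - center) / 45.0) ** 2)
    comp[nir] += 0.08 * np.sin(2 * np.pi * (mat_idx + 1) * (lam - MATERIAL_MIN_NM)
                               / (top - MATERIAL_MIN_NM))
    return comp


def make_plastic_scene(spec: SceneSpec, n_objects: int | None = None,
                       materials: list[str] | None = None,
                       colors: list[str] | None = None) -> ScenePair:
    """Shaped regions whose color varies only in the VNIR range and whose
    material varies only in the NIR range.

    Each object carries a (material, color) combination; by default every
    combination is present once, which guarantees regions that collide in
    VNIR-only (same color, different material) and in NIR-only (same
    material, different color) — the joint problem needs both ranges.
    Three ground truths are returned: color (C classes), material (M
    classes) and material-color (one class per present combination).
    """
    materials = materials or ["ABS", "PLA", "PETG"]
    colors = colors or ["red", "blue", "white"]
    n_m, n_c = len(materials), len(colors)
    if n_m < 2 or n_c < 2:
        raise ValueError("need at least 2 materials and 2 colors")
    combos = [(m, c) for m in range(n_m) for c in range(n_c)]
    if n_objects is None:
        n_objects = len(combos)
    if n_objects < 1:
        raise ValueError("need at least one object")
    assignment = [combos[i % len(combos)] for i in range(n_objects)]

    rng = _rng(spec.seed, 3)
    vr, vc = spec.vnir_dims
    side = int(math.ceil(math.sqrt(n_objects)))
    cell_r, cell_c = vr // side, vc // side
    if min(cell_r, cell_c) < 6:
        raise ValueError(f"{n_objects} objects do not fit a {vr}x{vc} canvas")
    color_lbl = np.zeros((vr, vc), dtype=np.int64)
    mat_lbl = np.zeros((vr, vc), dtype=np.int64)
    mc_lbl = np.zeros((vr, vc), dtype=np.int64)
    obj_id = np.zeros((vr, vc), dtype=np.int64)       # 0 background, 1..n objects
    cells = [(i, j) for i in range(side) for j in range(side)]
    rng.shuffle(cells)
    present_combos: list[tuple[int, int]] = []
    yy, xx = np.mgrid[0:vr, 0:vc]
    for k, ((mi, ci), (gi, gj)) in enumerate(zip(assignment, cells)):
        r0, c0 = gi * cell_r, gj * cell_c
        cy = r0 + cell_r / 2 + rng.uniform(-1, 1)
        cx = c0 + cell_c / 2 + rng.uniform(-1, 1)
        radius = 0.5 * min(cell_r, cell_c) * rng.uniform(0.55, 0.75)
        if rng.random() < 0.5:
            mask = ((xx - cx) ** 2 + (yy - cy) ** 2) <= radius ** 2
        else:
            mask = (np.abs(xx - cx) <= radius) & (np.abs(yy - cy) <= radius)
        obj_id[mask] = k + 1
        color_lbl[mask] = ci + 1
        mat_lbl[mask] = mi + 1
        if (mi, ci) not in present_combos:
            present_combos.append((mi, ci))
        mc_lbl[mask] = present_combos.index((mi, ci)) + 1

    sig_rng = _rng(spec.seed, 4)
    noise = spec.noise()
    full_grid = np.concatenate([spec.vnir_grid, spec.nir_grid])
    base_full = 0.45 + 0.1 * np.cos(np.pi * (full_grid - full_grid[0])
                                    / (full_grid[-1] - full_grid[0]))
    bg_full = _smooth_signature(full_grid, sig_rng, 0.1, 0.25)
    nv = len(spec.vnir_grid)

    # NIR frame samples the same object map through the true transform
    true_t = spec.true_transform or _nir_scaling_transform(spec)
    nr, nc_ = spec.nir_dims
    nyy, nxx = np.mgrid[0:nr, 0:nc_]
    mapped = true_t.apply(np.column_stack([nxx.ravel(), nyy.ravel()]).astype(float))
    mr = np.clip(np.round(mapped[:, 1]).astype(int), 0, vr - 1)
    mc = np.clip(np.round(mapped[:, 0]).astype(int), 0, vc - 1)
    obj_id_nir = obj_id[mr, mc].reshape(nr, nc_)

    cubes = {}
    for name, grid, ids, base, bg, modality, stream in [
            ("vnir", spec.vnir_grid, obj_id, base_full[:nv], bg_full[:nv], "VNIR", 31),
            ("nir", spec.nir_grid, obj_id_nir, base_full[nv:], bg_full[nv:], "NIR", 32)]:
        spectra = np.empty((n_objects + 1, len(grid)))
        spectra[0] = bg
        for k, (mi, ci) in enumerate(assignment):
            spectra[k + 1] = (base + _color_component(grid, ci, n_c)
                              + _material_component(grid, mi, n_m))
        ideal = spectra[ids]
        cube = HSCube(np.clip(ideal, 0.0, None), grid.copy(), modality,
                      {"scene": "plastic"})
        cubes[name] = sensor_capture(cube, noise, _rng(spec.seed, stream))

    combo_names = [f"{materials[m]}-{colors[c]}" for m, c in present_combos]
    return ScenePair(
        cubes["vnir"], cubes["nir"],
        vnir_labels=LabelMap(mc_lbl, combo_names),
        true_transform=true_t,
        color_gt=LabelMap(color_lbl, list(colors)),
        material_gt=LabelMap(mat_lbl, list(materials)),
        material_color_gt=LabelMap(mc_lbl, combo_names),
        meta={"scene": "plastic", "seed": spec.seed, "materials": list(materials),
              "colors": list(colors),
              "assignment": [[int(m), int(c)] for m, c in assignment]})


def _nir_scaling_transform(spec: SceneSpec) -> TransformModel:
    """Affine scaling that maps NIR pixel coordinates onto the VNIR frame
    (the default geometry when no misalignment is requested)."""
    vr, vc = spec.vnir_dims
    nr, nc = spec.nir_dims
    m = np.diag([(vc - 1) / (nc - 1), (vr - 1) / (nr - 1), 1.0])
    return TransformModel("affine", m, {"technique": "synthetic_truth"})
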