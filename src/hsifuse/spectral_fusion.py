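"""Spectral band trimming and VNIR-NIR spectrum fusion.

Push-broom sensors are unreliable at their spectral extremes, so before
fusing the two cameras' spectra each camera's *operating bandwidth* is
determined from two repeat captures of the same scene:

* the absolute relative difference percentage ``RD = 100 |a - b| /
  ((a + b) / 2)`` is computed per pixel and band, and its per-band mean
  over pixels (``rd_mean``) traces a "bathtub" curve — low where the
  sensor is repeatable, high at the noisy extremes;
* the band-average of that curve (``average_rd_mean``) is the threshold:
  the initial cutoff is the first band (from the low-wavelength end) where
  ``rd_mean`` stays at or below the threshold for a run of consecutive
  bands, and the final cutoff is found symmetrically from the top.

Fusion then crops each cube to its cutoffs, bilinearly upsamples /
registers the NIR segment onto the VNIR grid (done upstream), applies a
per-pixel reflectance offset so the NIR segment meets the VNIR segment at
the same level, concatenates the two segments leaving an explicit
wavelength gap (never interpolated across, so the NIR segment keeps its
native variance), and finally min-max normalizes every pixel spectrum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .core_data import HSCube, LabelMap, crop_bands, minmax_normalize_pixels

logger = logging.getLogger("hsifuse")


class CutoffError(RuntimeError):
    """Raised when no operating bandwidth satisfies the threshold rule."""


@dataclass
class RDCurve:
    """Per-band relative-difference statistics between two repeat captures."""

    wavelengths: np.ndarray
    rd_mean: np.ndarray        # mean over pixels, percent
    rd_std: np.ndarray         # std over pixels, percent
    average_rd_mean: float     # band mean of rd_mean, the cutoff threshold
    n_excluded: int = 0        # elements with a + b = 0, excluded from stats

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.rd_mean = np.asarray(self.rd_mean, dtype=float)
        self.rd_std = np.asarray(self.rd_std, dtype=float)
        if np.any(self.rd_mean < 0):
            raise ValueError("rd_mean must be non-negative")
        if not np.isclose(self.average_rd_mean, self.rd_mean.mean(), atol=1e-9):
            raise ValueError("average_rd_mean must equal mean(rd_mean)")


@dataclass
class CutoffResult:
    """Selected operating bandwidth of one camera."""

    initial_nm: float
    final_nm: float
    initial_idx: int
    final_idx: int
    curve: RDCurve | None = None

    def __post_init__(self) -> None:
        if self.initial_nm >= self.final_nm:
            raise ValueError("initial cutoff must be below final cutoff")


@dataclass
class FusedCube:
    """Two-segment fused spectrum with an explicit wavelength gap."""

    cube: HSCube
    segment_boundary: int          # index of the first NIR-origin band
    gap_nm: tuple[float, float]    # excluded wavelength interval
    offset_applied: float          # mean per-pixel reflectance offset

    def __post_init__(self) -> None:
        wl = self.cube.wavelengths
        if np.any(np.diff(wl) <= 0):
            raise ValueError("fused wavelengths must be strictly increasing")
        lo, hi = self.gap_nm
        if np.any((wl > lo) & (wl < hi)):
            raise ValueError("no fused band may lie inside the gap")

    def write(self, path: str | Path) -> None:
        from .core_data import write_envi
        path = Path(path)
        write_envi(self.cube, path)
        path.with_suffix(path.suffix + ".fusion.json").write_text(json.dumps({
            "segment_boundary": int(self.segment_boundary),
            "gap_nm": [float(g) for g in self.gap_nm],
            "offset_applied": float(self.offset_applied),
        }, indent=2))


# ---------------------------------------------------------------------------
# Relative difference and cutoffs
# ---------------------------------------------------------------------------

def relative_difference(capture1: HSCube, capture2: HSCube) -> RDCurve:
    """RD statistics between two captures of the same static scene.

    ``RD = 100 |a - b| / ((a + b) / 2)`` per element (symmetric in the two
    captures); elements where ``a + b = 0`` are excluded and counted.
    ``rd_mean[b]`` is the mean over all pixels at band ``b``.
    """
    if capture1.shape != capture2.shape or not np.allclose(
            capture1.wavelengths, capture2.wavelengths):
        raise ValueError("captures must share dims and wavelength grid")
    a = capture1.data.astype(float)
    b = capture2.data.astype(float)
    mean_ab = (a + b) / 2.0
    valid = mean_ab > 0
    n_excluded = int(valid.size - valid.sum())
    rd = np.zeros_like(a)
    rd[valid] = 100.0 * np.abs(a[valid] - b[valid]) / mean_ab[valid]
    counts = valid.sum(axis=(0, 1))
    counts = np.maximum(counts, 1)
    rd_sum = np.where(valid, rd, 0.0).sum(axis=(0, 1))
    rd_mean = rd_sum / counts
    # per-band std over valid pixels
    sq = np.where(valid, (rd - rd_mean[None, None, :]) ** 2, 0.0).sum(axis=(0, 1))
    rd_std = np.sqrt(sq / counts)
    return RDCurve(capture1.wavelengths.copy(), rd_mean, rd_std,
                   float(rd_mean.mean()), n_excluded)


def find_cutoffs(curve: RDCurve, run_length: int = 5) -> CutoffResult:
    """Operating-bandwidth cutoffs from an RD curve.

    The initial cutoff is the first band, scanning from the low-wavelength
    end, where ``rd_mean <= average_rd_mean`` holds for ``run_length``
    consecutive bands (the run requirement rejects single-band threshold
    crossings inside the noisy edge); the final cutoff is symmetric from
    the high end.  Scaling the whole curve by a positive constant leaves
    the cutoffs unchanged, since the threshold scales with it.
    """
    thr = curve.average_rd_mean
    ok = curve.rd_mean <= thr
    n = len(ok)
    if run_length < 1 or run_length > n:
        raise ValueError("run_length must be in [1, n_bands]")
    runs = np.convolve(ok.astype(int), np.ones(run_length, dtype=int), mode="valid")
    starts = np.flatnonzero(runs == run_length)   # i where ok[i:i+W] all true
    if starts.size == 0:
        raise CutoffError(
            f"no run of {run_length} bands stays below the average RD threshold "
            f"({thr:.3g}%)")
    initial = int(starts[0])
    final = int(starts[-1]) + run_length - 1
    return CutoffResult(float(curve.wavelengths[initial]), float(curve.wavelengths[final]),
                        initial, final, curve)


def fixed_cutoffs(cube: HSCube, lo_nm: float, hi_nm: float) -> CutoffResult:
    """A cutoff result pinned to configured wavelengths (nearest bands on
    the cube's grid) — for running with data-derived defaults such as the
    435/901 nm VNIR and 956/1638 nm NIR operating ranges."""
    i0 = int(np.searchsorted(cube.wavelengths, lo_nm, side="left"))
    i1 = int(np.searchsorted(cube.wavelengths, hi_nm, side="right")) - 1
    if i0 >= i1:
        raise ValueError("fixed cutoff range retains no bands")
    return CutoffResult(float(cube.wavelengths[i0]), float(cube.wavelengths[i1]), i0, i1)


# ---------------------------------------------------------------------------
# Upsampling and label transfer
# ---------------------------------------------------------------------------

def upsample_bilinear(nir: HSCube, target_dims: tuple[int, int]) -> HSCube:
    """Upsample every band to ``target_dims`` by bilinear interpolation over
    the nearest 2x2 neighbourhood.

    Corner-aligned mapping: target pixel ``(i, j)`` samples source
    coordinate ``(i * (R_s - 1) / (R_t - 1), j * (C_s - 1) / (C_t - 1))``,
    so corner spectra are preserved exactly and linear ramps are
    reproduced analytically.  Downsampling is out of scope.
    """
    rows_t, cols_t = target_dims
    rows_s, cols_s = nir.shape[:2]
    if rows_t < rows_s or cols_t < cols_s:
        raise ValueError("target dims must be >= source dims (upsampling only)")
    rr = np.arange(rows_t) * (rows_s - 1) / (rows_t - 1)
    cc = np.arange(cols_t) * (cols_s - 1) / (cols_t - 1)
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    coords = np.stack([grid_r.ravel(), grid_c.ravel()])
    out = np.empty((rows_t, cols_t, nir.n_bands))
    for b in range(nir.n_bands):
        out[:, :, b] = map_coordinates(nir.data[:, :, b].astype(float), coords,
                                       order=1, mode="nearest").reshape(rows_t, cols_t)
    meta = dict(nir.meta)
    meta["upsampled_from"] = (rows_s, cols_s)
    return HSCube(out, nir.wavelengths.copy(), nir.modality, meta)


def transfer_labels(vnir_labels: LabelMap, registered_grid_dims: tuple[int, int]) -> LabelMap:
    """Carry the VNIR labeling onto the co-registered grid.

    Once the NIR cube is upsampled and registered onto the VNIR frame the
    grids coincide and labels copy 1:1; any residual resampling uses
    nearest-neighbour (labels are categorical, no new values may appear).
    """
    rows_t, cols_t = registered_grid_dims
    rows_s, cols_s = vnir_labels.labels.shape
    if (rows_t, cols_t) == (rows_s, cols_s):
        return LabelMap(vnir_labels.labels.copy(), list(vnir_labels.class_names))
    rr = np.round(np.arange(rows_t) * (rows_s - 1) / (rows_t - 1)).astype(int)
    cc = np.round(np.arange(cols_t) * (cols_s - 1) / (cols_t - 1)).astype(int)
    return LabelMap(vnir_labels.labels[np.ix_(rr, cc)], list(vnir_labels.class_names))


# ---------------------------------------------------------------------------
# Reflectance offset and fusion
# ---------------------------------------------------------------------------

def reflectance_offset(vnir_pixel_spectrum: np.ndarray, nir_pixel_spectrum: np.ndarray,
                       k_bands: int = 5) -> float:
    """Additive level correction for the NIR segment of one pixel.

    ``offset = mean(last k_bands of the VNIR segment) - mean(first k_bands
    of the NIR segment)``: adding it to the NIR segment makes the two
    segments meet at the same reflectance level across the gap.
    """
    v = np.asarray(vnir_pixel_spectrum, dtype=float)
    n = np.asarray(nir_pixel_spectrum, dtype=float)
    if k_bands < 1 or k_bands > len(v) or k_bands > len(n):
        raise ValueError("k_bands must be within both segment lengths")
    return float(v[-k_bands:].mean() - n[:k_bands].mean())


def fuse(vnir: HSCube, nir_registered: HSCube, vnir_cut: CutoffResult,
         nir_cut: CutoffResult, k_bands: int = 5, normalize: bool = True) -> FusedCube:
    """Fuse co-registered VNIR and NIR cubes into one broadband cube.

    Both cubes are cropped to their operating bandwidths; each pixel's NIR
    segment is shifted by that pixel's reflectance offset; the segments
    are concatenated with the wavelength gap ``(vnir final, nir initial)``
    recorded (and never filled in); finally every pixel spectrum is
    min-max normalized unless ``normalize=False``.
    """
    if vnir.shape[:2] != nir_registered.shape[:2]:
        raise ValueError("cubes must be co-registered to equal spatial dims")
    if vnir_cut.final_nm >= nir_cut.initial_nm:
        raise ValueError(
            f"retained ranges overlap: VNIR ends at {vnir_cut.final_nm} nm, "
            f"NIR starts at {nir_cut.initial_nm} nm (gap must be non-negative)")
    v = crop_bands(vnir, vnir_cut.initial_nm, vnir_cut.final_nm)
    n = crop_bands(nir_registered, nir_cut.initial_nm, nir_cut.final_nm)
    if k_bands > v.n_bands or k_bands > n.n_bands:
        raise ValueError("k_bands exceeds a retained segment length")
    offsets = (v.data[:, :, -k_bands:].mean(axis=2)
               - n.data[:, :, :k_bands].mean(axis=2))
    fused_data = np.concatenate([v.data, n.data + offsets[:, :, None]], axis=2)
    wavelengths = np.concatenate([v.wavelengths, n.wavelengths])
    meta = {"fused_from": (vnir.modality, nir_registered.modality),
            "vnir_bands": v.n_bands, "nir_bands": n.n_bands,
            "k_bands": k_bands, "mean_offset": float(offsets.mean())}
    cube = HSCube(fused_data, wavelengths, "FUSED", meta)
    if normalize:
        cube = minmax_normalize_pixels(cube)
    logger.info("fuse: %d VNIR + %d NIR bands, gap (%.1f, %.1f) nm",
                v.n_bands, n.n_bands, vnir_cut.final_nm, nir_cut.initial_nm)
    return FusedCube(cube, v.n_bands, (vnir_cut.final_nm, nir_cut.initial_nm),
                     float(offsets.mean()))
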