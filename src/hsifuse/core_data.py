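"""Hyperspectral cube data model and pre-processing primitives.

A hyperspectral (HS) cube is a 3-D reflectance array indexed ``(row, col,
band)`` together with a strictly increasing wavelength axis in nanometres.
This module provides the cube container, ENVI-style raw+header I/O,
white/dark reflectance calibration, spectral smoothing, band-range cropping,
pseudo-RGB / grayscale rendering and per-pixel min-max normalization — the
pre-processing stages that every downstream registration / fusion step
builds on.

Conventions
-----------
* spatial indexing is 0-based ``(row, col)``; wavelengths are band centers
  in nm, strictly increasing;
* reflectance is dimensionless and non-negative after calibration;
* ENVI dialect: BSQ by default, little-endian, float32 reflectance.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import uniform_filter1d

logger = logging.getLogger("hsifuse")

#: Modalities a cube can carry.  FUSED marks a two-segment spectrum.
MODALITIES = ("VNIR", "NIR", "FUSED")

#: Default pseudo-RGB band centers (nm) for VNIR cubes.
VNIR_RGB_NM = (708.0, 539.0, 470.0)

#: Rec. 601 luminance weights used by :func:`to_grayscale`.
_LUMA = np.array([0.299, 0.587, 0.114])

# ENVI numeric data-type codes we read/write.
_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


class FormatError(ValueError):
    """Raised when an on-disk header contradicts itself or the raw file."""


def _validate_wavelengths(wl: np.ndarray) -> np.ndarray:
    wl = np.asarray(wl, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise ValueError("wavelength axis needs at least 2 entries")
    if not np.all(np.isfinite(wl)) or np.any(wl <= 0):
        raise ValueError("wavelengths must be finite and positive")
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    return wl


@dataclass
class HSCube:
    """Calibrated reflectance cube with a wavelength axis.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Reflectance values, dimensionless, ``>= 0`` once calibrated.
    wavelengths : ndarray, shape (bands,)
        Band-center wavelengths in nm, strictly increasing.
    modality : {"VNIR", "NIR", "FUSED"}
    meta : dict
        Free-form provenance (capture id, calibration state, ...).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    modality: str = "VNIR"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows, cols, bands)")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError("cube spatial dims must be at least 2x2")
        self.wavelengths = _validate_wavelengths(self.wavelengths)
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band count {self.data.shape[2]} != wavelength count {self.wavelengths.size}"
            )
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")

    # -- convenience -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, nm: float) -> int:
        """Index of the band whose center is nearest to ``nm``."""
        return int(np.argmin(np.abs(self.wavelengths - nm)))

    def copy(self) -> "HSCube":
        return HSCube(self.data.copy(), self.wavelengths.copy(), self.modality, dict(self.meta))


@dataclass
class CalibrationRefs:
    """White / dark reference captures on the same band grid as the raw image.

    ``white`` and ``dark`` may be full cubes ``(rows, cols, bands)``,
    push-broom frames ``(cols, bands)`` broadcast along the scan axis, or
    per-band vectors ``(bands,)``.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark references must share a shape")
        frac = np.mean(self.white > self.dark)
        if frac < 0.99:
            raise ValueError(
                f"white > dark on only {frac:.1%} of elements; sensor references look swapped"
            )

    def broadcast(self, shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Broadcast references to the raw cube's full shape."""
        def _b(a: np.ndarray) -> np.ndarray:
            if a.ndim == 3:
                return np.broadcast_to(a, shape)
            if a.ndim == 2:  # (cols, bands) frame, constant along scan rows
                return np.broadcast_to(a[None, :, :], shape)
            if a.ndim == 1:  # per-band vector
                return np.broadcast_to(a[None, None, :], shape)
            raise ValueError("reference must be 1-D, 2-D or 3-D")
        return _b(self.white), _b(self.dark)


@dataclass
class LabelMap:
    """Per-pixel integer class labels; 0 means unlabeled."""

    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0 (0 = unlabeled)")
        if self.labels.max() > len(self.class_names):
            raise ValueError("nonzero label exceeds number of class names")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


# ---------------------------------------------------------------------------
# ENVI-style I/O
# ---------------------------------------------------------------------------

def _header_path(path: Path) -> Path:
    return path if path.suffix == ".hdr" else path.with_suffix(path.suffix + ".hdr")


def _parse_envi_header(text: str) -> dict:
    """Parse the ``key = value`` / ``key = { ... }`` ENVI header grammar."""
    fields: dict[str, str] = {}
    body = text.strip()
    if body.startswith("ENVI"):
        body = body[4:]
    i = 0
    lines = body.splitlines()
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and "}" not in val:
            parts = [val]
            while i < len(lines):
                parts.append(lines[i])
                if "}" in lines[i]:
                    i += 1
                    break
                i += 1
            val = " ".join(p.strip() for p in parts)
        fields[key] = val
    return fields


def write_envi(cube: HSCube, path: str | Path, interleave: str = "bsq") -> None:
    """Write ``cube`` as ENVI raw binary plus a ``.hdr`` text header.

    The header declares samples/lines/bands, data type, interleave, byte
    order and the wavelength list (nm, 4 decimals).  ``interleave`` is one
    of ``bsq`` (band-sequential, default), ``bil`` or ``bip``.
    """
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    path = Path(path)
    rows, cols, bands = cube.shape
    data = cube.data
    if data.dtype not in _DTYPE_CODES:
        data = data.astype(np.float32)
    # in-memory layout is BIP (row, col, band); permute for the others
    if interleave == "bsq":
        ondisk = np.transpose(data, (2, 0, 1))
    elif interleave == "bil":
        ondisk = np.transpose(data, (0, 2, 1))
    else:
        ondisk = data
    path.parent.mkdir(parents=True, exist_ok=True)
    ondisk.astype(ondisk.dtype.newbyteorder("<")).tofile(path)
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{hsifuse {cube.modality} cube}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[data.dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
        f"modality = {cube.modality}\n"
    )
    _header_path(path).write_text(header)


def read_envi(path: str | Path) -> HSCube:
    """Read an ENVI raw+header pair written by :func:`write_envi` (or any
    BSQ/BIL/BIP little-endian file with a standard text header)."""
    path = Path(path)
    if path.suffix == ".hdr":
        hdr_path, raw_path = path, path.with_suffix("")
    else:
        hdr_path, raw_path = _header_path(path), path
    if not hdr_path.exists():
        raise FormatError(f"missing header file {hdr_path}")
    if not raw_path.exists():
        raise FormatError(f"missing raw file {raw_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    for required in ("samples", "lines", "bands", "data type", "interleave"):
        if required not in fields:
            raise FormatError(f"header missing required field '{required}'")
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported data type code {code}")
    if int(fields.get("byte order", "0")) != 0:
        raise FormatError("only little-endian (byte order = 0) files are supported")
    interleave = fields["interleave"].lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unsupported interleave '{interleave}'")
    if "wavelength" not in fields:
        raise FormatError("header missing required field 'wavelength'")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array([float(w) for w in wl_text.split(",") if w.strip()])
    if wavelengths.size != bands:
        raise FormatError(
            f"header declares bands = {bands} but lists {wavelengths.size} wavelengths"
        )
    dtype = np.dtype(_ENVI_DTYPES[code]).newbyteorder("<")
    flat = np.fromfile(raw_path, dtype=dtype)
    if flat.size != rows * cols * bands:
        raise FormatError(
            f"raw file holds {flat.size} values, header implies {rows * cols * bands}"
        )
    if interleave == "bsq":
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:
        data = flat.reshape(rows, cols, bands)
    modality = fields.get("modality", "VNIR").strip()
    if modality not in MODALITIES:
        modality = "VNIR"
    return HSCube(np.ascontiguousarray(data), wavelengths, modality, {"source": str(raw_path)})


def write_labelmap(lm: LabelMap, path: str | Path) -> None:
    """Write a label map as a palette PNG (palette index = class id) plus a
    JSON sidecar with the class names."""
    path = Path(path)
    img = Image.fromarray(lm.labels.astype(np.uint8), mode="P")
    # deterministic palette: 0 black, classes spread over hue-ish ramp
    palette = [0, 0, 0]
    for c in range(1, 256):
        palette += [(37 * c) % 256, (91 * c) % 256, (151 * c) % 256]
    img.putpalette(palette)
    img.save(path)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"class_names": lm.class_names}))


def read_labelmap(path: str | Path) -> LabelMap:
    path = Path(path)
    labels = np.asarray(Image.open(path), dtype=np.int64)
    names = json.loads(path.with_suffix(".json").read_text())["class_names"]
    return LabelMap(labels, names)


# ---------------------------------------------------------------------------
# Calibration and spectral pre-processing
# ---------------------------------------------------------------------------

def calibrate(
    raw: HSCube,
    refs: CalibrationRefs,
    clip_max: float = 2.0,
    eps: float = 1e-6,
) -> HSCube:
    """Convert raw sensor counts to reflectance with white/dark references.

    Reflectance is ``R = (raw - dark) / (white - dark)`` element-wise,
    which removes the illumination profile and the sensor dark current.
    Where the denominator is ``<= eps`` (dead pixels) it is floored at
    ``eps`` so a handful of bad elements cannot poison downstream
    registration metrics; the result is clipped to ``[0, clip_max]``.
    """
    white, dark = refs.broadcast(raw.shape)
    denom = white - dark
    n_bad = int(np.count_nonzero(denom <= eps))
    if n_bad:
        logger.warning("calibrate: %d elements with (white - dark) <= %g floored", n_bad, eps)
        denom = np.maximum(denom, eps)
    refl = np.clip((raw.data - dark) / denom, 0.0, clip_max)
    meta = dict(raw.meta)
    meta.update(calibrated=True, calib_floored_elements=n_bad, calib_clip_max=clip_max)
    return HSCube(refl, raw.wavelengths.copy(), raw.modality, meta)


def smooth_spectra(cube: HSCube, window: int = 5) -> HSCube:
    """Moving-average filter along the band axis only.

    Reduces the high-frequency spectral noise the sensor injects while
    leaving spatial content untouched.  ``window`` must be odd; ``window=1``
    is the identity.  Band edges use reflected padding; on interior bands
    the output is exactly the mean of the surrounding ``window`` samples.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window > cube.n_bands:
        raise ValueError("smoothing window exceeds band count")
    if window == 1:
        return cube.copy()
    out = uniform_filter1d(cube.data.astype(float), size=window, axis=2, mode="reflect")
    meta = dict(cube.meta)
    meta["smoothing_window"] = window
    return HSCube(out, cube.wavelengths.copy(), cube.modality, meta)


def crop_bands(cube: HSCube, lo_nm: float, hi_nm: float) -> HSCube:
    """Retain bands with ``lo_nm <= wavelength <= hi_nm`` (inclusive)."""
    if lo_nm >= hi_nm:
        raise ValueError("lo_nm must be < hi_nm")
    keep = (cube.wavelengths >= lo_nm) & (cube.wavelengths <= hi_nm)
    if keep.sum() < 2:
        raise ValueError(f"band range [{lo_nm}, {hi_nm}] nm retains fewer than 2 bands")
    meta = dict(cube.meta)
    meta["band_crop_nm"] = (float(lo_nm), float(hi_nm))
    return HSCube(cube.data[:, :, keep], cube.wavelengths[keep], cube.modality, meta)


def _scale01(channel: np.ndarray) -> np.ndarray:
    lo, hi = channel.min(), channel.max()
    if hi - lo <= 0:
        return np.full_like(channel, 0.5, dtype=float)
    return (channel - lo) / (hi - lo)


def pseudo_rgb(cube: HSCube, bands_nm: tuple[float, float, float] | None = None) -> np.ndarray:
    """False-color 3-channel rendering in ``[0, 1]``.

    VNIR cubes map the configured red/green/blue band centers (defaults
    708/539/470 nm) to the channels; NIR and FUSED cubes replicate a single
    mid-band plane into all three channels, since any color assignment in
    those ranges is arbitrary.  Each channel is min-max scaled.
    """
    if cube.n_bands < 3:
        raise ValueError("pseudo-RGB needs at least 3 bands")
    if bands_nm is None and cube.modality == "VNIR":
        bands_nm = VNIR_RGB_NM
    if bands_nm is None:
        mid = cube.data[:, :, cube.n_bands // 2]
        return np.dstack([_scale01(mid)] * 3)
    idx = [cube.band_index(nm) for nm in bands_nm]
    return np.dstack([_scale01(cube.data[:, :, i]) for i in idx])


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance of a 3-channel image, deterministic, in [0, 1]."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (rows, cols, 3) image")
    return rgb @ _LUMA


def minmax_normalize_pixels(cube: HSCube) -> HSCube:
    """Scale every pixel's spectrum to min 0 / max 1.

    Homogenizes reflectance levels across pixels before clustering or
    classification.  Constant-spectrum pixels map to all-zero spectra and
    are counted in ``meta['constant_pixels']`` (one warning overall).
    """
    d = cube.data.astype(float)
    lo = d.min(axis=2, keepdims=True)
    hi = d.max(axis=2, keepdims=True)
    span = hi - lo
    flat = span[:, :, 0] <= 0
    n_flat = int(np.count_nonzero(flat))
    if n_flat:
        warnings.warn(f"{n_flat} constant-spectrum pixels normalized to zeros")
    out = np.where(span > 0, (d - lo) / np.where(span > 0, span, 1.0), 0.0)
    meta = dict(cube.meta)
    meta.update(pixel_normalized=True, constant_pixels=n_flat)
    return HSCube(out, cube.wavelengths.copy(), cube.modality, meta)
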