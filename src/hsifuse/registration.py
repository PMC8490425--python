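"""Spatial registration of the NIR cube onto the VNIR frame.

The two push-broom cameras see the same scene from slightly different
geometry, so before any spectral fusion the NIR image (the *moving* image)
must be mapped onto the VNIR image (the *fixed* image).  This module
provides:

* :class:`TransformModel` — translation / similarity / affine / projective
  transforms as homogeneous 3x3 matrices acting on ``(col, row, 1)``;
* image-similarity metrics (SSIM, mutual information, Pearson correlation);
* intensity-based registration (mean-squares objective over a multi-
  resolution pyramid);
* feature-based registration: scale-covariant blob detection (or a stable-
  extremal-region detector), descriptor ratio-test matching, and MSAC —
  a RANSAC variant with a truncated squared-error cost — for robust
  transform estimation;
* warping and common-ROI cropping of full cubes;
* a coarse-to-fine search over spectral band pairs for the pair that
  registers best, and cross-dataset selection of a reusable transform
  model by lowest SSIM interquartile range.

Coordinates are 0-based pixel centers, ordered ``(col, row)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, stats
from skimage.feature import SIFT
from skimage.measure import label as cc_label, regionprops
from skimage.metrics import structural_similarity
from skimage.transform import ProjectiveTransform, estimate_transform, rescale
from skimage.transform import warp as sk_warp

from .core_data import HSCube, pseudo_rgb, to_grayscale

logger = logging.getLogger("hsifuse")

TRANSFORM_KINDS = ("translation", "similarity", "affine", "projective")

#: minimal number of point correspondences needed per transform kind
MIN_SAMPLES = {"translation": 1, "similarity": 2, "affine": 3, "projective": 4}


class RegistrationError(RuntimeError):
    """Raised when a registration stage cannot produce a model."""


@dataclass
class TransformModel:
    """A 2-D geometric transform mapping moving-frame ``(col, row, 1)`` to
    the fixed frame, stored as a homogeneous 3x3 matrix."""

    kind: str
    matrix: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(f"kind must be one of {TRANSFORM_KINDS}")
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("matrix must be 3x3")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("matrix must be invertible")
        if self.kind != "projective" and not np.allclose(self.matrix[2], [0, 0, 1]):
            raise ValueError(f"{self.kind} transform must have bottom row (0, 0, 1)")
        if abs(self.matrix[2, 2]) > 1e-12:
            self.matrix = self.matrix / self.matrix[2, 2]

    @classmethod
    def identity(cls, kind: str = "translation") -> "TransformModel":
        return cls(kind, np.eye(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(N, 2)`` moving-frame (col, row) points into the fixed frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.hstack([pts, np.ones((len(pts), 1))]) @ self.matrix.T
        return hom[:, :2] / hom[:, 2:3]

    def inverse(self) -> "TransformModel":
        return TransformModel(self.kind, np.linalg.inv(self.matrix), dict(self.provenance))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "kind": self.kind,
            "matrix": self.matrix.tolist(),
            "provenance": self.provenance,
        }, indent=2, default=str))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransformModel":
        d = json.loads(Path(path).read_text())
        return cls(d["kind"], np.array(d["matrix"]), d.get("provenance", {}))


@dataclass
class MatchSet:
    """Paired point correspondences, (col, row), 0-based."""

    fixed_points: np.ndarray
    moving_points: np.ndarray
    descriptor_distances: np.ndarray

    def __post_init__(self) -> None:
        self.fixed_points = np.atleast_2d(np.asarray(self.fixed_points, dtype=float))
        self.moving_points = np.atleast_2d(np.asarray(self.moving_points, dtype=float))
        self.descriptor_distances = np.asarray(self.descriptor_distances, dtype=float)
        if len(self.fixed_points) != len(self.moving_points):
            raise ValueError("point lists must pair up")

    def __len__(self) -> int:
        return len(self.fixed_points)


@dataclass
class Features:
    """Keypoints ``(N, 2)`` in (col, row) plus row-wise descriptors."""

    keypoints: np.ndarray
    descriptors: np.ndarray

    def __len__(self) -> int:
        return len(self.keypoints)


@dataclass
class BandSearchResult:
    metric: str
    grid: np.ndarray                 # coarse score matrix
    vnir_bands: np.ndarray           # band indices along grid rows
    nir_bands: np.ndarray            # band indices along grid cols
    step_vnir: int
    step_nir: int
    best_pair: tuple[int, int]       # (vnir band index, nir band index)
    best_score: float
    fine_grid: np.ndarray | None = None
    fine_vnir_bands: np.ndarray | None = None
    fine_nir_bands: np.ndarray | None = None

    def to_files(self, stem: str | Path) -> None:
        stem = Path(stem)
        np.savetxt(stem.with_suffix(".csv"), self.grid, delimiter=",")
        stem.with_suffix(".json").write_text(json.dumps({
            "metric": self.metric,
            "step_vnir": self.step_vnir,
            "step_nir": self.step_nir,
            "best_pair": [int(b) for b in self.best_pair],
            "best_score": float(self.best_score),
        }, indent=2))


# ---------------------------------------------------------------------------
# Similarity metrics
# ---------------------------------------------------------------------------

def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("metrics need two 2-D images of equal shape")
    return a, b


def ssim(a: np.ndarray, b: np.ndarray, win_size: int = 7) -> float:
    """Structural similarity over a uniform ``win_size`` window.

    Windowed means, sample variances and covariance enter the standard
    two-constant SSIM formula; the joint intensity range of both images is
    used as the data range so the metric is symmetric in its arguments.
    """
    a, b = _check_pair(a, b)
    if min(a.shape) < win_size:
        win_size = min(a.shape) // 2 * 2 - 1
        if win_size < 3:
            raise ValueError("images too small for SSIM")
    joint_range = max(a.max(), b.max()) - min(a.min(), b.min())
    if joint_range <= 0:
        return 1.0  # two identical constant images
    return float(structural_similarity(a, b, win_size=win_size, data_range=joint_range))


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 64) -> float:
    """Mutual information (bits) of the joint intensity histogram.

    ``MI(x, x)`` equals the Shannon entropy of x's binned marginal.
    """
    a, b = _check_pair(a, b)
    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def pcc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of pixel intensities over the flattened images."""
    a, b = _check_pair(a, b)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Pearson correlation undefined for a constant image")
    return float(np.corrcoef(a.ravel(), b.ravel())[0, 1])


def iqr(x: np.ndarray) -> float:
    """Interquartile range with linear-interpolation quartiles."""
    return float(np.percentile(x, 75) - np.percentile(x, 25))


METRICS = {"ssim": ssim, "mi": mutual_information, "pcc": pcc}


# ---------------------------------------------------------------------------
# Transform fitting from correspondences
# ---------------------------------------------------------------------------

def fit_transform(fixed_pts: np.ndarray, moving_pts: np.ndarray, kind: str) -> TransformModel:
    """Least-squares transform mapping moving points onto fixed points."""
    fixed_pts = np.atleast_2d(fixed_pts)
    moving_pts = np.atleast_2d(moving_pts)
    if kind == "translation":
        t = fixed_pts.mean(axis=0) - moving_pts.mean(axis=0)
        m = np.eye(3)
        m[0, 2], m[1, 2] = t
        return TransformModel(kind, m)
    skind = {"similarity": "similarity", "affine": "affine", "projective": "projective"}[kind]
    tf = estimate_transform(skind, src=moving_pts, dst=fixed_pts)
    if not tf:  # FailedEstimation is falsy on degenerate configurations
        raise RegistrationError("degenerate point configuration")
    m = np.asarray(tf.params)
    if not np.all(np.isfinite(m)) or abs(np.linalg.det(m)) < 1e-12:
        raise RegistrationError("degenerate point configuration")
    if kind != "projective":
        m = m.copy()
        m[2] = [0.0, 0.0, 1.0]
    return TransformModel(kind, m)


# ---------------------------------------------------------------------------
# Intensity-based registration
# ---------------------------------------------------------------------------

def _params_to_matrix(params: np.ndarray, kind: str) -> np.ndarray:
    m = np.eye(3)
    if kind == "translation":
        m[0, 2], m[1, 2] = params
    elif kind == "similarity":
        tx, ty, rot, s = params
        c, sn = np.cos(rot), np.sin(rot)
        m[:2, :2] = s * np.array([[c, -sn], [sn, c]])
        m[0, 2], m[1, 2] = tx, ty
    elif kind == "affine":
        m[0] = params[0], params[1], params[4]
        m[1] = params[2], params[3], params[5]
    else:
        raise ValueError("intensity-based registration supports translation/similarity/affine")
    return m


def _init_params(kind: str) -> np.ndarray:
    return {"translation": np.zeros(2),
            "similarity": np.array([0.0, 0.0, 0.0, 1.0]),
            "affine": np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])}[kind]


def warp_image(img: np.ndarray, t: TransformModel, out_shape: tuple[int, int],
               order: int = 1, cval: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Resample a 2-D image through ``t`` (moving -> fixed) by inverse
    mapping with bilinear interpolation.  Returns (warped, valid_mask)."""
    inv = ProjectiveTransform(np.linalg.inv(t.matrix))
    warped = sk_warp(img.astype(float), inverse_map=inv, output_shape=out_shape,
                     order=order, cval=cval, preserve_range=True)
    ones = sk_warp(np.ones_like(img, dtype=float), inverse_map=inv,
                   output_shape=out_shape, order=1, cval=0.0, preserve_range=True)
    return warped, ones > 0.999


def register_intensity(fixed: np.ndarray, moving: np.ndarray, kind: str = "affine",
                       levels: int = 3, maxiter: int = 200) -> TransformModel:
    """Intensity-based registration by mean-squares minimisation.

    The mean squared intensity difference between the fixed image and the
    warped moving image (over the valid overlap) is minimised with a
    derivative-free Powell search, coarse-to-fine over a ``levels``-deep
    half-resolution pyramid.  Non-convergence returns the best iterate with
    ``provenance['converged'] = False``.
    """
    if kind not in ("translation", "similarity", "affine"):
        raise ValueError("intensity-based registration supports translation/similarity/affine")
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    pyramid = [(fixed, moving)]
    for _ in range(levels - 1):
        f, m = pyramid[-1]
        if min(f.shape) < 32 or min(m.shape) < 32:
            break
        pyramid.append((rescale(f, 0.5, anti_aliasing=True),
                        rescale(m, 0.5, anti_aliasing=True)))
    params = _init_params(kind)
    converged = True
    score = np.inf
    for level, (f, m) in enumerate(reversed(pyramid)):
        if level > 0:  # translations double when resolution doubles
            if kind == "translation":
                params = params * 2
            elif kind == "similarity":
                params = params * np.array([2.0, 2.0, 1.0, 1.0])
            else:
                params = params * np.array([1, 1, 1, 1, 2.0, 2.0])

        def cost(p: np.ndarray, f: np.ndarray = f, m: np.ndarray = m) -> float:
            try:
                t = TransformModel(kind, _params_to_matrix(p, kind))
            except ValueError:
                return 1e12
            w, mask = warp_image(m, t, f.shape)
            if mask.sum() < 0.25 * mask.size:
                return 1e12
            return float(np.mean((f[mask] - w[mask]) ** 2))

        res = optimize.minimize(cost, params, method="Powell",
                                options={"maxiter": maxiter, "xtol": 1e-4, "ftol": 1e-8})
        params = res.x
        score = float(res.fun)
        converged = converged and bool(res.success)
    return TransformModel(kind, _params_to_matrix(params, kind), {
        "technique": "intensity", "objective": "mean_squares",
        "optimizer": "powell_pyramid", "levels": len(pyramid),
        "score": score, "converged": converged,
    })


# ---------------------------------------------------------------------------
# Feature detection and matching
# ---------------------------------------------------------------------------

def _to_unit(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)


def _patch_descriptor(img: np.ndarray, col: float, row: float, radius: float,
                      size: int = 12) -> np.ndarray | None:
    """Mean/std-normalized intensity patch sampled on a square around the
    point, scaled to the region radius (makes the descriptor scale-covariant)."""
    from scipy.ndimage import map_coordinates
    half = max(radius, 3.0)
    g = np.linspace(-half, half, size)
    cc, rr = np.meshgrid(col + g, row + g)
    if cc.min() < -half or rr.min() < -half:
        return None
    patch = map_coordinates(img, [rr.ravel(), cc.ravel()], order=1, mode="nearest")
    std = patch.std()
    if std < 1e-9:
        return None
    return (patch - patch.mean()) / std


def _detect_mser(img: np.ndarray, n_levels: int = 24, min_area: int = 15,
                 max_area_frac: float = 0.25, stability: float = 0.7) -> Features:
    """Stable-extremal-region detector: threshold the image at a stack of
    levels (both polarities), keep connected components whose area is stable
    across neighbouring levels, and describe each region by a normalized
    patch around its centroid scaled to its equivalent radius."""
    img = _to_unit(img)
    levels = np.linspace(0.08, 0.92, n_levels)
    max_area = max_area_frac * img.size
    found: dict[tuple[int, int], tuple[float, float, float]] = {}
    for polarity in (1, -1):
        work = img if polarity == 1 else 1.0 - img
        areas_by_level = []
        for t in levels:
            lbl = cc_label(work > t)
            regs = {r.label: r for r in regionprops(lbl)
                    if min_area <= r.area <= max_area}
            areas_by_level.append((lbl, regs))
        for k in range(1, n_levels - 1):
            lbl, regs = areas_by_level[k]
            for r in regs.values():
                rr, cc = (int(round(c)) for c in r.centroid)
                # area of the component containing the centroid one level up/down
                prev_lbl, prev_regs = areas_by_level[k - 1]
                next_lbl, next_regs = areas_by_level[k + 1]
                pl = prev_lbl[rr, cc] if 0 <= rr < lbl.shape[0] and 0 <= cc < lbl.shape[1] else 0
                nl = next_lbl[rr, cc] if 0 <= rr < lbl.shape[0] and 0 <= cc < lbl.shape[1] else 0
                if pl == 0 or nl == 0 or pl not in prev_regs or nl not in next_regs:
                    continue
                a_prev, a_next = prev_regs[pl].area, next_regs[nl].area
                if (a_prev - a_next) / r.area <= stability:
                    key = (rr // 2, cc // 2)
                    radius = float(np.sqrt(r.area / np.pi))
                    if key not in found:
                        found[key] = (r.centroid[1], r.centroid[0], radius)
    kps, descs = [], []
    for col, row, radius in found.values():
        d = _patch_descriptor(img, col, row, radius)
        if d is not None:
            kps.append((col, row))
            descs.append(d)
    if not kps:
        return Features(np.empty((0, 2)), np.empty((0, 144)))
    return Features(np.array(kps), np.array(descs))


def detect_features(img: np.ndarray, detector: str = "blob") -> Features:
    """Detect keypoints with descriptors.

    ``"blob"`` (default, accepted alias ``"surf"``/``"sift"``) runs a
    scale-covariant difference-of-Gaussians blob detector with gradient-
    histogram descriptors.  ``"mser"`` extracts stable extremal regions and
    describes their centroids with scale-normalized patches.  A constant
    image yields an empty feature set.
    """
    img = np.asarray(img, dtype=float)
    if min(img.shape) < 16:
        raise ValueError("image too small for feature detection (needs >= 16x16)")
    detector = detector.lower()
    if detector in ("blob", "surf", "sift", "fallback"):
        det = SIFT()
        try:
            det.detect_and_extract(_to_unit(img))
        except RuntimeError:  # no extrema found (e.g. constant image)
            return Features(np.empty((0, 2)), np.empty((0, 128)))
        # skimage keypoints come back (row, col); flip to (col, row)
        kps = det.keypoints[:, ::-1].astype(float)
        return Features(kps, det.descriptors.astype(float))
    if detector == "mser":
        return _detect_mser(img)
    raise ValueError(f"unknown detector {detector!r}")


def match_features(fixed: Features, moving: Features, ratio: float = 0.7,
                   mutual: bool = True) -> MatchSet:
    """Nearest-neighbour descriptor matching with Lowe's distance-ratio test
    and (by default) mutual-best filtering."""
    if len(fixed) == 0 or len(moving) == 0:
        raise RegistrationError("cannot match empty feature sets")
    from scipy.spatial.distance import cdist
    d = cdist(fixed.descriptors, moving.descriptors)
    pairs, dists = [], []
    nearest_back = np.argmin(d, axis=0)
    for i in range(len(fixed)):
        order = np.argsort(d[i])
        j = order[0]
        best = d[i, j]
        second = d[i, order[1]] if len(order) > 1 else np.inf
        if best > ratio * second:
            continue
        if mutual and nearest_back[j] != i:
            continue
        pairs.append((i, j))
        dists.append(best)
    if not pairs:
        return MatchSet(np.empty((0, 2)), np.empty((0, 2)), np.empty(0))
    fi, mi = zip(*pairs)
    fp = fixed.keypoints[list(fi)]
    mp = moving.keypoints[list(mi)]
    dd = np.array(dists)
    # multi-orientation keypoints duplicate coordinates; keep one pair each
    _, unique_idx = np.unique(np.hstack([fp, mp]), axis=0, return_index=True)
    unique_idx = np.sort(unique_idx)
    return MatchSet(fp[unique_idx], mp[unique_idx], dd[unique_idx])


# ---------------------------------------------------------------------------
# MSAC robust estimation
# ---------------------------------------------------------------------------

def _is_degenerate(t: TransformModel, moving: np.ndarray) -> bool:
    """Reject physically impossible hypotheses: a collapsing linear part, or
    a projective denominator that changes sign / vanishes over the data
    (points passing through the plane at infinity)."""
    det2 = np.linalg.det(t.matrix[:2, :2])
    if not np.isfinite(det2) or abs(det2) < 1e-3 or abs(det2) > 1e3:
        return True
    w = moving @ t.matrix[2, :2] + t.matrix[2, 2]
    return bool(np.any(w < 0.1))


def estimate_msac(matches: MatchSet, kind: str = "projective", seed: int = 0,
                  trials: int = 1000, inlier_tol_px: float = 1.5) -> TransformModel:
    """M-estimator Sample Consensus fit of a transform to noisy matches.

    Random minimal samples are drawn ``trials`` times; each hypothesis is
    scored with the truncated squared-error cost ``sum(min(r^2, tol^2))``
    (the MSAC cost, which unlike plain RANSAC grades inliers by their
    residual).  The lowest-cost hypothesis's inliers get a final
    least-squares refit.  Deterministic given ``seed``.
    """
    n = len(matches)
    m = MIN_SAMPLES[kind]
    if n < m:
        raise RegistrationError(f"{kind} needs >= {m} matches, got {n}")
    rng = np.random.default_rng(seed)
    fixed, moving = matches.fixed_points, matches.moving_points
    tol2 = inlier_tol_px ** 2
    best_cost, best_inliers = np.inf, None
    for _ in range(trials):
        idx = rng.choice(n, size=m, replace=False)
        try:
            t = fit_transform(fixed[idx], moving[idx], kind)
        except (RegistrationError, ValueError):
            continue
        if _is_degenerate(t, moving):
            continue
        r2 = np.sum((t.apply(moving) - fixed) ** 2, axis=1)
        cost = float(np.minimum(r2, tol2).sum())
        if cost < best_cost:
            best_cost = cost
            best_inliers = r2 < tol2
    if best_inliers is None or best_inliers.sum() < m:
        raise RegistrationError("MSAC found no model with enough inliers")
    # refit on inliers, re-classify, and iterate until the inlier set is stable
    refit = fit_transform(fixed[best_inliers], moving[best_inliers], kind)
    for _ in range(10):
        r2 = np.sum((refit.apply(moving) - fixed) ** 2, axis=1)
        new_inliers = r2 < tol2
        if new_inliers.sum() < m or np.array_equal(new_inliers, best_inliers):
            break
        best_inliers = new_inliers
        refit = fit_transform(fixed[best_inliers], moving[best_inliers], kind)
    r = np.sqrt(np.sum((refit.apply(moving[best_inliers]) - fixed[best_inliers]) ** 2, axis=1))
    refit.provenance.update({
        "technique": "msac", "kind": kind, "seed": seed, "trials": trials,
        "inlier_tol_px": inlier_tol_px, "n_matches": n,
        "n_inliers": int(best_inliers.sum()), "inlier_rmse_px": float(np.sqrt(np.mean(r ** 2))),
        "inlier_mask": best_inliers.tolist(),
    })
    return refit


def register_features(fixed: np.ndarray, moving: np.ndarray, detector: str = "blob",
                      kind: str = "projective", seed: int = 0, trials: int = 1000,
                      inlier_tol_px: float = 1.5, ratio: float = 0.7) -> TransformModel:
    """Feature-based registration: detect -> match -> MSAC."""
    f_feat = detect_features(fixed, detector)
    m_feat = detect_features(moving, detector)
    matches = match_features(f_feat, m_feat, ratio=ratio)
    if len(matches) < MIN_SAMPLES[kind]:
        raise RegistrationError(
            f"only {len(matches)} matches survived the ratio test; need {MIN_SAMPLES[kind]}")
    t = estimate_msac(matches, kind, seed=seed, trials=trials, inlier_tol_px=inlier_tol_px)
    t.provenance.update({"technique": "feature", "detector": detector,
                         "n_fixed_features": len(f_feat), "n_moving_features": len(m_feat)})
    return t


# ---------------------------------------------------------------------------
# Cube warping and common-ROI cropping
# ---------------------------------------------------------------------------

def warp(moving_cube: HSCube, t: TransformModel,
         out_dims: tuple[int, int]) -> tuple[HSCube, np.ndarray]:
    """Resample every band of ``moving_cube`` into the fixed frame.

    Inverse mapping with bilinear interpolation; pixels that fall outside
    the moving image get the fill value 0 and are flagged False in the
    returned validity mask.
    """
    inv = ProjectiveTransform(np.linalg.inv(t.matrix))
    rows, cols = out_dims
    out = np.empty((rows, cols, moving_cube.n_bands), dtype=float)
    for b in range(moving_cube.n_bands):
        out[:, :, b] = sk_warp(moving_cube.data[:, :, b].astype(float), inverse_map=inv,
                               output_shape=out_dims, order=1, cval=0.0, preserve_range=True)
    ones = sk_warp(np.ones(moving_cube.shape[:2]), inverse_map=inv,
                   output_shape=out_dims, order=1, cval=0.0, preserve_range=True)
    mask = ones > 0.999
    meta = dict(moving_cube.meta)
    meta["warped_by"] = t.matrix.tolist()
    return HSCube(out, moving_cube.wavelengths.copy(), moving_cube.modality, meta), mask


def largest_interior_rectangle(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Largest axis-aligned all-True rectangle, as (row0, row1, col0, col1)
    half-open slices.  Histogram-of-heights + monotonic stack, O(rows*cols)."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    heights = np.zeros(cols, dtype=int)
    best = (0, 0, 0, 0)
    best_area = 0
    for r in range(rows):
        heights = np.where(mask[r], heights + 1, 0)
        stack: list[int] = []
        for c in range(cols + 1):
            h = heights[c] if c < cols else 0
            while stack and heights[stack[-1]] > h:
                height = heights[stack.pop()]
                left = stack[-1] + 1 if stack else 0
                area = height * (c - left)
                if area > best_area:
                    best_area = area
                    best = (r - height + 1, r + 1, left, c)
            stack.append(c)
    if best_area == 0:
        raise RegistrationError("mask has no valid region")
    return best


def crop_common_roi(fixed: HSCube, warped: HSCube,
                    mask: np.ndarray) -> tuple[HSCube, HSCube]:
    """Crop both cubes to the largest rectangle fully inside the valid mask,
    so downstream fusion only sees pixels both cameras actually observed."""
    if fixed.shape[:2] != warped.shape[:2] or mask.shape != fixed.shape[:2]:
        raise ValueError("fixed, warped and mask must share spatial dims")
    r0, r1, c0, c1 = largest_interior_rectangle(mask)
    if r1 - r0 < 2 or c1 - c0 < 2:
        raise RegistrationError("valid overlap region is degenerate")
    def _crop(c: HSCube) -> HSCube:
        meta = dict(c.meta)
        meta["roi"] = (r0, r1, c0, c1)
        return HSCube(c.data[r0:r1, c0:c1], c.wavelengths.copy(), c.modality, meta)
    return _crop(fixed), _crop(warped)


# ---------------------------------------------------------------------------
# Coarse-to-fine band search
# ---------------------------------------------------------------------------

def _band_pair_score(vnir: HSCube, nir: HSCube, i: int, j: int, metric: str,
                     detector: str, kind: str, seed: int,
                     trials: int) -> float:
    va = _to_unit(vnir.data[:, :, i])
    nb = _to_unit(nir.data[:, :, j])
    t = register_features(va, nb, detector=detector, kind=kind, seed=seed, trials=trials)
    wb, mask = warp_image(nb, t, va.shape)
    r0, r1, c0, c1 = largest_interior_rectangle(mask)
    if r1 - r0 < 8 or c1 - c0 < 8:
        raise RegistrationError("overlap too small to score")
    return METRICS[metric](va[r0:r1, c0:c1], wb[r0:r1, c0:c1])


def coarse_to_fine_band_search(vnir: HSCube, nir: HSCube,
                               coarse_steps: tuple[int, int] = (7, 3),
                               metric: str = "ssim", seed: int = 0,
                               detector: str = "blob", kind: str = "projective",
                               trials: int = 200) -> BandSearchResult:
    """Find the (VNIR band, NIR band) pair that registers best.

    Stage 1 scores a coarse grid of band pairs (default steps 7 VNIR / 3
    NIR): each pair is converted to unit-range grayscale, registered
    feature-based, and scored with ``metric`` on the common overlap.
    Stage 2 repeats at one-band steps inside the neighbourhood of the
    coarse optimum.  Band pairs whose registration fails are recorded as
    NaN and excluded from the argmax; ties break toward the lowest index
    pair.  SSIM is the selection metric by default because it is the only
    one of the three that rewards structural (not just intensity)
    agreement.
    """
    sv, sn = coarse_steps
    vbands = np.arange(0, vnir.n_bands, sv)
    nbands = np.arange(0, nir.n_bands, sn)
    grid = np.full((len(vbands), len(nbands)), np.nan)
    for a, i in enumerate(vbands):
        for b, j in enumerate(nbands):
            try:
                grid[a, b] = _band_pair_score(vnir, nir, int(i), int(j), metric,
                                              detector, kind, seed, trials)
            except RegistrationError:
                continue
    if np.all(np.isnan(grid)):
        raise RegistrationError("no band pair registered successfully")
    a, b = np.unravel_index(np.nanargmax(grid), grid.shape)
    ci, cj = int(vbands[a]), int(nbands[b])
    # fine stage: one-band steps inside the winning coarse neighbourhood
    fv = np.arange(max(0, ci - sv + 1), min(vnir.n_bands, ci + sv))
    fn = np.arange(max(0, cj - sn + 1), min(nir.n_bands, cj + sn))
    fine = np.full((len(fv), len(fn)), np.nan)
    for a2, i in enumerate(fv):
        for b2, j in enumerate(fn):
            if i == ci and j == cj:
                fine[a2, b2] = grid[a, b]
                continue
            try:
                fine[a2, b2] = _band_pair_score(vnir, nir, int(i), int(j), metric,
                                                detector, kind, seed, trials)
            except RegistrationError:
                continue
    a2, b2 = np.unravel_index(np.nanargmax(fine), fine.shape)
    best_pair = (int(fv[a2]), int(fn[b2]))
    return BandSearchResult(metric=metric, grid=grid, vnir_bands=vbands, nir_bands=nbands,
                            step_vnir=sv, step_nir=sn, best_pair=best_pair,
                            best_score=float(fine[a2, b2]), fine_grid=fine,
                            fine_vnir_bands=fv, fine_nir_bands=fn)


# ---------------------------------------------------------------------------
# Transform-model selection across a dataset
# ---------------------------------------------------------------------------

def _pair_gray(pair) -> tuple[np.ndarray, np.ndarray]:
    """Grayscale fixed/moving images from a scene pair (duck-typed: needs
    ``.vnir`` and ``.nir`` cubes)."""
    return (to_grayscale(pseudo_rgb(pair.vnir)), to_grayscale(pseudo_rgb(pair.nir)))


def select_transform_model(candidates: list[TransformModel], dataset: list,
                           metric: str = "ssim", reps: int = 1000,
                           alpha: float = 0.05) -> tuple[TransformModel, dict]:
    """Pick one reusable transform model for a whole dataset.

    Each candidate is applied to every scene pair and scored with
    ``metric`` on the common overlap; the winner is the candidate with the
    lowest interquartile range (the most *consistent* model, not the
    highest-mean one).  The report includes a paired two-tailed t-test of
    the winner against the highest-mean candidate at level ``alpha``.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    if len(candidates) == 1:
        return candidates[0], {"scores": None, "note": "single candidate"}
    if len(dataset) < 2:
        raise ValueError("need at least two dataset scene pairs")
    scores = np.full((len(candidates), len(dataset)), np.nan)
    for ci, t in enumerate(candidates):
        for di, pair in enumerate(dataset):
            f, m = _pair_gray(pair)
            w, mask = warp_image(m, t, f.shape)
            try:
                r0, r1, c0, c1 = largest_interior_rectangle(mask)
                scores[ci, di] = METRICS[metric](f[r0:r1, c0:c1], w[r0:r1, c0:c1])
            except RegistrationError:
                scores[ci, di] = -1.0
    iqrs = np.array([iqr(s) for s in scores])
    means = scores.mean(axis=1)
    winner = int(np.argmin(iqrs))
    top_mean = int(np.argmax(means))
    if winner == top_mean:
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_rel(scores[winner], scores[top_mean])
    report = {
        "metric": metric, "scores": scores, "iqr": iqrs, "mean": means,
        "winner": winner, "highest_mean": top_mean,
        "t_stat": float(t_stat), "p_value": float(p_val),
        "significant": bool(p_val < alpha), "alpha": alpha, "reps": reps,
    }
    logger.info("select_transform_model: winner=%d iqr=%.4f (p=%.3f vs highest mean)",
                winner, iqrs[winner], p_val)
    return candidates[winner], report
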