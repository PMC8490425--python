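"""Segmentation / classification harness for comparing data modalities.

The point of fusing the two cameras is discrimination power: problems
whose signal lives in the visible range (color), in the near-infrared
(material), or in both at once (material-color).  This module provides

* unsupervised segmentation (K-means, K-medoids, hierarchical K-means)
  with Jaccard-based cluster-to-class assignment,
* supervised pixel classification (SVM, random forest, KNN) with a
  coarse (and, for SVM, coarse-to-fine) hyperparameter search on a
  validation split,
* overlap and accuracy metrics plus paired Student's t-tests,
* :func:`compare_modalities`, which runs the whole harness on VNIR-only,
  NIR-only and fused data over the color / material / material-color
  problems and reports mean scores with significance flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .core_data import HSCube, LabelMap, minmax_normalize_pixels
from .registration import warp
from .spectral_fusion import FusedCube, fixed_cutoffs, fuse

logger = logging.getLogger("hsifuse")

SEG_ALGORITHMS = ("kmeans", "kmedoids", "hierarchical_kmeans")
CLF_KINDS = ("svm", "rf", "knn")
PROBLEMS = ("color", "material", "material_color")
DATA_TYPES = ("VNIR", "NIR", "FUSED")


@dataclass
class SegmentationConfig:
    algorithm: str = "kmeans"
    K: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in SEG_ALGORITHMS:
            raise ValueError(f"algorithm must be one of {SEG_ALGORITHMS}")
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass
class ClassifierConfig:
    kind: str = "svm"
    seed: int = 0
    # coarse grids; SVM gets an extra fine 3x3 refinement around the optimum
    svm_c_grid: tuple = tuple(10.0 ** e for e in range(-3, 4))
    svm_gamma_grid: tuple = tuple(10.0 ** e for e in range(-3, 4))
    rf_trees_grid: tuple = (50, 100, 200, 300, 400, 500)
    knn_k_grid: tuple = tuple(range(1, 26, 2))

    def __post_init__(self) -> None:
        if self.kind not in CLF_KINDS:
            raise ValueError(f"kind must be one of {CLF_KINDS}")


@dataclass
class EvalReport:
    """Per-problem, per-data-type scores with paired-test significance."""

    scores: dict = field(default_factory=dict)   # scores[problem][dtype] -> 1-D array
    means: dict = field(default_factory=dict)
    stds: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)  # (problem, a, b) -> p of "a > b"
    significant: dict = field(default_factory=dict)
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for problem, per_type in self.scores.items():
            for dtype, vals in per_type.items():
                for i, v in enumerate(np.atleast_1d(vals)):
                    rows.append({"problem": problem, "data_type": dtype,
                                 "run": i, "score": float(v)})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Unsupervised segmentation
# ---------------------------------------------------------------------------

def _pixel_matrix(cube: HSCube | FusedCube) -> tuple[np.ndarray, tuple[int, int]]:
    c = cube.cube if isinstance(cube, FusedCube) else cube
    rows, cols, bands = c.shape
    return c.data.reshape(rows * cols, bands).astype(float), (rows, cols)


def _kmedoids(X: np.ndarray, k: int, rng: np.random.Generator,
              max_iter: int = 30, max_fit: int = 2000) -> np.ndarray:
    """Alternating k-medoids (Euclidean).  Medoids are fit on a subsample
    of at most ``max_fit`` pixels, then all pixels are assigned."""
    n = len(X)
    fit_idx = rng.choice(n, size=min(n, max_fit), replace=False)
    Xf = X[fit_idx]
    med = Xf[rng.choice(len(Xf), size=k, replace=False)]
    for _ in range(max_iter):
        d = np.linalg.norm(Xf[:, None, :] - med[None, :, :], axis=2)
        assign = np.argmin(d, axis=1)
        new_med = med.copy()
        for j in range(k):
            members = Xf[assign == j]
            if len(members) == 0:
                continue
            within = np.linalg.norm(members[:, None, :] - members[None, :, :], axis=2)
            new_med[j] = members[np.argmin(within.sum(axis=1))]
        if np.allclose(new_med, med):
            break
        med = new_med
    d_all = np.linalg.norm(X[:, None, :] - med[None, :, :], axis=2)
    return np.argmin(d_all, axis=1)


def _hierarchical_kmeans(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Recursively bisect the cluster with the largest inertia with 2-means
    until ``k`` clusters exist."""
    labels = np.zeros(len(X), dtype=int)
    next_id = 1
    while next_id < k:
        inertias = {}
        for c in np.unique(labels):
            member = X[labels == c]
            if len(member) < 2:
                inertias[c] = -np.inf
                continue
            inertias[c] = float(((member - member.mean(axis=0)) ** 2).sum())
        target = max(inertias, key=inertias.get)
        if not np.isfinite(inertias[target]):
            break  # nothing splittable; degenerate
        members = np.flatnonzero(labels == target)
        km = KMeans(n_clusters=2, random_state=seed, n_init=5).fit(X[members])
        labels[members[km.labels_ == 1]] = next_id
        next_id += 1
    return labels


def segment(cube: HSCube | FusedCube, cfg: SegmentationConfig) -> np.ndarray:
    """Cluster pixel spectra into ``cfg.K`` groups; returns a 2-D integer
    cluster-id map.  Deterministic given ``cfg.seed``."""
    X, dims = _pixel_matrix(cube)
    if cfg.K > len(X):
        raise ValueError("K exceeds pixel count")
    if cfg.K == 1:
        return np.zeros(dims, dtype=int)
    n_distinct = len(np.unique(X, axis=0))
    if cfg.K > n_distinct:
        logger.warning("segment: K=%d exceeds %d distinct spectra; clusters degenerate",
                       cfg.K, n_distinct)
    rng = np.random.default_rng(cfg.seed)
    if cfg.algorithm == "kmeans":
        labels = KMeans(n_clusters=cfg.K, random_state=cfg.seed, n_init=10).fit_predict(X)
    elif cfg.algorithm == "kmedoids":
        labels = _kmedoids(X, cfg.K, rng)
    else:
        labels = _hierarchical_kmeans(X, cfg.K, cfg.seed)
    return labels.reshape(dims)


def jaccard(pred: LabelMap, gt: LabelMap) -> tuple[dict[int, float], float]:
    """Per-class intersection-over-union and its mean, scored only over
    ground-truth-labeled pixels.  Classes absent from both maps are
    undefined and excluded."""
    if pred.labels.shape != gt.labels.shape:
        raise ValueError("label maps must share dims")
    labeled = gt.labels > 0
    p = pred.labels[labeled]
    g = gt.labels[labeled]
    scores: dict[int, float] = {}
    for c in range(1, gt.n_classes + 1):
        inter = np.count_nonzero((p == c) & (g == c))
        union = np.count_nonzero((p == c) | (g == c))
        if union == 0:
            continue
        scores[c] = inter / union
    if not scores:
        raise ValueError("no class present in either map")
    return scores, float(np.mean(list(scores.values())))


def clusters_to_classes(clusters: np.ndarray, gt: LabelMap) -> LabelMap:
    """Map cluster ids to ground-truth classes by Jaccard.

    For every (class, cluster) pair the Jaccard overlap on labeled pixels
    is computed; assignments are made greedily in descending Jaccard with
    each cluster and each class used at most once.  Pixels of unassigned
    clusters stay unlabeled; empty or zero-overlap clusters are never
    assigned.
    """
    if clusters.shape != gt.labels.shape:
        raise ValueError("cluster map and ground truth must share dims")
    labeled = gt.labels > 0
    if not np.any(labeled):
        raise ValueError("ground truth has no labeled pixels")
    g = gt.labels[labeled]
    k = clusters[labeled]
    pairs = []
    for c in range(1, gt.n_classes + 1):
        in_c = g == c
        if not np.any(in_c):
            continue
        for j in np.unique(clusters):
            in_j = k == j
            union = np.count_nonzero(in_c | in_j)
            inter = np.count_nonzero(in_c & in_j)
            if union and inter:
                pairs.append((inter / union, c, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_c: set[int] = set()
    used_j: set[int] = set()
    mapping: dict[int, int] = {}
    for score, c, j in pairs:
        if c in used_c or j in used_j:
            continue
        mapping[j] = c
        used_c.add(c)
        used_j.add(j)
    out = np.zeros_like(gt.labels)
    for j, c in mapping.items():
        out[clusters == j] = c
    return LabelMap(out, list(gt.class_names))


def overall_accuracy(pred: LabelMap, gt: LabelMap) -> float:
    """Fraction of ground-truth-labeled pixels predicted correctly."""
    if pred.labels.shape != gt.labels.shape:
        raise ValueError("label maps must share dims")
    labeled = gt.labels > 0
    if not np.any(labeled):
        raise ValueError("ground truth has no labeled pixels")
    return float(np.mean(pred.labels[labeled] == gt.labels[labeled]))


def paired_ttest(a: np.ndarray, b: np.ndarray, alternative: str = "greater") -> tuple[float, float]:
    """Paired Student's t-test of ``a`` vs ``b``; ``alternative='greater'``
    tests mean(a - b) > 0.  Identical samples give t = 0, p = 1 (one-
    tailed) / p = 1 (two-tailed by convention here)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or np.allclose(a, b):
        return 0.0, 1.0
    res = stats.ttest_rel(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Supervised classification
# ---------------------------------------------------------------------------

def _build_clf(cfg: ClassifierConfig, params: dict):
    if cfg.kind == "svm":
        return SVC(kernel="rbf", C=params["C"], gamma=params["gamma"],
                   random_state=cfg.seed)
    if cfg.kind == "rf":
        return RandomForestClassifier(n_estimators=params["n_estimators"],
                                      random_state=cfg.seed, n_jobs=1)
    return KNeighborsClassifier(n_neighbors=params["k"])


def _coarse_grid(cfg: ClassifierConfig) -> list[dict]:
    if cfg.kind == "svm":
        return [{"C": c, "gamma": g} for c in cfg.svm_c_grid for g in cfg.svm_gamma_grid]
    if cfg.kind == "rf":
        return [{"n_estimators": n} for n in cfg.rf_trees_grid]
    return [{"k": k} for k in cfg.knn_k_grid]


def _fine_grid_svm(best: dict) -> list[dict]:
    factors = (10 ** -0.5, 1.0, 10 ** 0.5)
    return [{"C": best["C"] * fc, "gamma": best["gamma"] * fg}
            for fc in factors for fg in factors]


def train_eval_classifier(train: tuple[np.ndarray, np.ndarray],
                          val: tuple[np.ndarray, np.ndarray],
                          test: tuple[np.ndarray, np.ndarray],
                          cfg: ClassifierConfig) -> dict:
    """Grid-search hyperparameters on the validation split, then evaluate
    the refit model on the test split only.

    SVM gets a coarse-to-fine search (a 3x3 half-decade refinement around
    the coarse optimum); RF and KNN use a single coarse pass.  Ties break
    toward the first grid entry, so the result is deterministic given the
    seed.  Returns the model plus chosen params and accuracies.
    """
    X_tr, y_tr = train
    X_va, y_va = val
    X_te, y_te = test
    classes = np.unique(y_tr)
    if len(classes) < 2:
        raise ValueError("training split needs at least 2 classes")

    def search(grid: list[dict]) -> tuple[dict, float]:
        best_p, best_acc = None, -1.0
        for params in grid:
            clf = _build_clf(cfg, params).fit(X_tr, y_tr)
            acc = float(np.mean(clf.predict(X_va) == y_va))
            if acc > best_acc:
                best_p, best_acc = params, acc
        return best_p, best_acc

    best, val_acc = search(_coarse_grid(cfg))
    if cfg.kind == "svm":
        fine_best, fine_acc = search(_fine_grid_svm(best))
        if fine_acc >= val_acc:
            best, val_acc = fine_best, fine_acc
    model = _build_clf(cfg, best).fit(X_tr, y_tr)
    test_acc = float(np.mean(model.predict(X_te) == y_te))
    return {"model": model, "params": best, "val_accuracy": val_acc,
            "test_accuracy": test_acc, "kind": cfg.kind, "seed": cfg.seed}


# ---------------------------------------------------------------------------
# Modality comparison
# ---------------------------------------------------------------------------

def _prepare_modalities(scene, edge_trim_frac: float = 0.1,
                        k_bands: int = 5) -> dict[str, HSCube]:
    """Build the three normalized data types from a scene pair: trimmed
    VNIR, trimmed+registered NIR (through the scene's true transform, on
    the VNIR grid), and their fusion."""
    vnir, nir = scene.vnir, scene.nir
    nir_reg, _ = warp(nir, scene.true_transform, vnir.shape[:2])

    def trim(cube: HSCube):
        n = cube.n_bands
        k = max(1, int(round(edge_trim_frac * n)))
        return fixed_cutoffs(cube, cube.wavelengths[k], cube.wavelengths[n - 1 - k])

    v_cut, n_cut = trim(vnir), trim(nir_reg)
    from .core_data import crop_bands
    v_trim = crop_bands(vnir, v_cut.initial_nm, v_cut.final_nm)
    n_trim = crop_bands(nir_reg, n_cut.initial_nm, n_cut.final_nm)
    fused = fuse(v_trim, n_trim,
                 fixed_cutoffs(v_trim, v_trim.wavelengths[0], v_trim.wavelengths[-1]),
                 fixed_cutoffs(n_trim, n_trim.wavelengths[0], n_trim.wavelengths[-1]),
                 k_bands=k_bands)
    return {"VNIR": minmax_normalize_pixels(v_trim),
            "NIR": minmax_normalize_pixels(n_trim),
            "FUSED": fused.cube}


def _problem_gt(scene, problem: str) -> LabelMap:
    gt = {"color": scene.color_gt, "material": scene.material_gt,
          "material_color": scene.material_color_gt}[problem]
    if gt is None:
        raise ValueError(f"scene has no ground truth for problem {problem!r}")
    return gt


def _split_pixels(cube: HSCube, gt: LabelMap, seed: int,
                  n_train: int = 60, n_val: int = 40, n_test: int = 100):
    """Stratified disjoint train/val/test pixel samples per class."""
    rng = np.random.default_rng(seed)
    X = cube.data.reshape(-1, cube.n_bands)
    y = gt.labels.ravel()
    parts = {"train": ([], []), "val": ([], []), "test": ([], [])}
    for c in np.unique(y):
        if c == 0:
            continue
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        need = n_train + n_val + n_test
        if len(idx) < need:
            # shrink proportionally for small classes, keeping all disjoint
            f = len(idx) / need
            nt, nv = max(2, int(n_train * f)), max(1, int(n_val * f))
            ns = len(idx) - nt - nv
        else:
            nt, nv, ns = n_train, n_val, n_test
        for name, sl in (("train", idx[:nt]), ("val", idx[nt:nt + nv]),
                         ("test", idx[nt + nv:nt + nv + ns])):
            parts[name][0].append(X[sl])
            parts[name][1].append(np.full(len(sl), c))
    return {k: (np.vstack(v[0]), np.concatenate(v[1])) for k, v in parts.items()}


def compare_modalities(scenes, problems=PROBLEMS, method: str = "svm",
                       seeds=(0,), edge_trim_frac: float = 0.1,
                       alpha: float = 0.05) -> EvalReport:
    """Run the full harness on VNIR / NIR / fused data per problem.

    ``scenes`` is a list of scene pairs with color / material /
    material-color ground truths (one scene also works).  ``method`` is a
    classifier kind ("svm" / "rf" / "knn") or a segmentation algorithm
    name prefixed with "seg:" (e.g. ``"seg:kmeans"``, scored by mean
    Jaccard).  Each (scene, seed) combination contributes one paired
    score per data type; clustering / split seeds are shared across data
    types so the paired one-tailed t-tests are valid.
    """
    if not isinstance(scenes, (list, tuple)):
        scenes = [scenes]
    report = EvalReport(alpha=alpha)
    per = {p: {d: [] for d in DATA_TYPES} for p in problems}
    for scene in scenes:
        data = _prepare_modalities(scene, edge_trim_frac=edge_trim_frac)
        for problem in problems:
            gt = _problem_gt(scene, problem)
            for seed in seeds:
                for dtype in DATA_TYPES:
                    cube = data[dtype]
                    if method.startswith("seg:"):
                        cfg = SegmentationConfig(method[4:], K=gt.n_classes, seed=seed)
                        clusters = segment(cube, cfg)
                        mapped = clusters_to_classes(clusters, gt)
                        _, score = jaccard(mapped, gt)
                    else:
                        splits = _split_pixels(cube, gt, seed)
                        res = train_eval_classifier(splits["train"], splits["val"],
                                                    splits["test"],
                                                    ClassifierConfig(method, seed=seed))
                        score = res["test_accuracy"]
                    per[problem][dtype].append(score)
    for problem in problems:
        report.scores[problem] = {d: np.array(v) for d, v in per[problem].items()}
        report.means[problem] = {d: float(np.mean(v)) for d, v in per[problem].items()}
        report.stds[problem] = {d: float(np.std(v)) for d, v in per[problem].items()}
        for a in DATA_TYPES:
            for b in DATA_TYPES:
                if a == b:
                    continue
                t, p = paired_ttest(report.scores[problem][a], report.scores[problem][b])
                report.p_values[(problem, a, b)] = p
                report.significant[(problem, a, b)] = bool(p < alpha)
    return report
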