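"""Texture-based living/dead cell classification.

Gray-level co-occurrence matrices (GLCM) are computed on quantized cell crops
and summarized by the 13 classical Haralick statistics (averaged over angles,
one block per offset distance); a random-forest ensemble is trained on these
features.  Evaluation retrains the forest under several seeds on a fixed
train/test split and reports per-seed accuracies, their mean +/- SD and the
confusion matrix of the first seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import graycomatrix
from sklearn.ensemble import RandomForestClassifier

__all__ = ["GLCMConfig", "EvalReport", "FEATURE_NAMES",
           "glcm", "haralick_features", "texture_features",
           "train_classifier", "evaluate"]

FEATURE_NAMES = (
    "angular_second_moment", "contrast", "correlation", "sum_of_squares_variance",
    "inverse_difference_moment", "sum_average", "sum_variance", "sum_entropy",
    "entropy", "difference_variance", "difference_entropy",
    "info_measure_correlation_1", "info_measure_correlation_2",
)


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 64
    distances: tuple = (1,)
    angles_deg: tuple = (0, 45, 90, 135)
    symmetric: bool = True
    normalize: bool = True
    robust_quantize: bool = False  # 1-99 percentile scaling instead of min-max

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be >= 1")


def _quantize(image: np.ndarray, cfg: GLCMConfig) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if cfg.robust_quantize:
        lo, hi = np.percentile(img, [1, 99])
    else:
        lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    q = np.clip((img - lo) / (hi - lo), 0.0, 1.0) * (cfg.levels - 1)
    return np.round(q).astype(np.uint8)


def glcm(image: np.ndarray, cfg: GLCMConfig = GLCMConfig()) -> np.ndarray:
    """Co-occurrence matrices, shape (levels, levels, n_distances, n_angles).

    The image is min-max quantized to ``cfg.levels`` gray levels; matrices are
    symmetrized and normalized to sum 1 per (distance, angle) if configured.
    """
    img = np.asarray(image)
    if img.shape[0] <= max(cfg.distances) or img.shape[1] <= max(cfg.distances):
        raise ValueError("image smaller than the largest co-occurrence offset")
    q = _quantize(img, cfg)
    angles = [np.deg2rad(a) for a in cfg.angles_deg]
    return graycomatrix(q, distances=list(cfg.distances), angles=angles,
                        levels=cfg.levels, symmetric=cfg.symmetric,
                        normed=cfg.normalize)


def _haralick_13(p: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of one normalized co-occurrence matrix."""
    L = p.shape[0]
    i = np.arange(L, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # p_{x+y}(k), k = 0..2L-2 and p_{x-y}(k), k = 0..L-1
    pxy_sum = np.zeros(2 * L - 1)
    np.add.at(pxy_sum, (ii + jj).astype(int).ravel(), p.ravel())
    pxy_diff = np.zeros(L)
    np.add.at(pxy_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    asm = float((p ** 2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    corr = (float((ii * jj * p).sum()) - mu_x * mu_y) / (sd_x * sd_y) \
        if sd_x > 0 and sd_y > 0 else 0.0
    variance = float(((ii - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    k_sum = np.arange(2 * L - 1, dtype=float)
    sum_avg = float((k_sum * pxy_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * pxy_sum).sum())
    sum_ent = ent(pxy_sum)
    entropy = ent(p.ravel())
    k_diff = np.arange(L, dtype=float)
    diff_avg = float((k_diff * pxy_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * pxy_diff).sum())
    diff_ent = ent(pxy_diff)

    # information measures of correlation
    hx, hy = ent(px), ent(py)
    mask = np.outer(px, py) > 0
    hxy1 = float(-(p[mask] * np.log(np.outer(px, py)[mask])).sum())
    op = np.outer(px, py)
    opm = op[op > 0]
    hxy2 = float(-(opm * np.log(opm)).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array([asm, contrast, corr, variance, idm, sum_avg, sum_var,
                     sum_ent, entropy, diff_var, diff_ent, imc1, imc2])


def haralick_features(matrices: np.ndarray, cfg: GLCMConfig = GLCMConfig()) -> np.ndarray:
    """13 Haralick statistics averaged over angles, one block per distance.

    ``matrices`` must be normalized (each (distance, angle) plane sums to 1).
    """
    m = np.asarray(matrices, dtype=float)
    if m.ndim != 4:
        raise ValueError("expected (levels, levels, n_distances, n_angles) matrices")
    sums = m.sum(axis=(0, 1))
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("matrices are not normalized; pass normalize=True to glcm()")
    blocks = []
    for d in range(m.shape[2]):
        feats = np.stack([_haralick_13(m[:, :, d, a]) for a in range(m.shape[3])])
        blocks.append(feats.mean(axis=0))
    return np.concatenate(blocks)


def texture_features(image: np.ndarray, cfg: GLCMConfig = GLCMConfig()) -> np.ndarray:
    """Convenience: quantize, co-occur, summarize one crop."""
    return haralick_features(glcm(image, cfg), cfg)


def train_classifier(features, labels, n_trees: int = 500, seed: int = 0):
    """Random forest with the customary defaults: 500 trees, sqrt(p) features
    per split, unlimited depth, bootstrap resampling, majority vote."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 10:
        raise ValueError("need at least 10 samples per class")
    clf = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                 random_state=seed)
    clf.fit(X, y)
    return clf


@dataclass(frozen=True)
class EvalReport:
    """Multi-seed classification evaluation (rows = true, cols = predicted)."""

    accuracies: tuple
    mean_accuracy: float
    sd_accuracy: float
    confusion: np.ndarray = field(repr=False, default=None)
    class_order: tuple = ("living", "dead")


def evaluate(train_features, train_labels, test_features, test_labels,
             seeds=range(10), n_trees: int = 500,
             class_order=("living", "dead")) -> EvalReport:
    """Retrain + test under each seed on the fixed split; summarize.

    The confusion matrix reported is the first seed's, with rows = true class
    and columns = predicted class in ``class_order``.
    """
    Xtr = np.asarray(train_features, dtype=float)
    Xte = np.asarray(test_features, dtype=float)
    ytr = np.asarray(train_labels)
    yte = np.asarray(test_labels)
    if set(np.unique(yte)) - set(np.unique(ytr)):
        raise ValueError("test labels contain classes absent from training")
    accs = []
    confusion = None
    for seed in seeds:
        clf = train_classifier(Xtr, ytr, n_trees=n_trees, seed=int(seed))
        pred = clf.predict(Xte)
        accs.append(float(np.mean(pred == yte)))
        if confusion is None:
            k = len(class_order)
            confusion = np.zeros((k, k), dtype=int)
            index = {c: i for i, c in enumerate(class_order)}
            for t, q in zip(yte, pred):
                confusion[index[t], index[q]] += 1
    accs = np.asarray(accs)
    sd = float(accs.std(ddof=1)) if len(accs) > 1 else 0.0
    return EvalReport(accuracies=tuple(accs), mean_accuracy=float(accs.mean()),
                      sd_accuracy=sd, confusion=confusion, class_order=tuple(class_order))
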