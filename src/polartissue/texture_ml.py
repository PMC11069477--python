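"""GLCM texture features and SVM classification of parameter maps.

The classification stage mirrors a standard texture-analysis protocol:
each 2D parameter map (DOP/DOLP/DOCP/anisotropy, or one Mueller element)
is augmented by horizontal and vertical flips (3 versions), cut into a
4×4 grid of 16 equal patches, and each patch is quantized to 8 gray
levels over the parameter's physical display range.  An 8×8 symmetric,
normalized gray-level co-occurrence matrix — averaged over the four
unit-distance offsets 0°/45°/90°/135° — yields 20 Haralick-style texture
statistics per patch.  With 4 normal + 4 tumour regions this gives
8 × 3 × 16 = 384 patch records per parameter (6144 over the 16 Mueller
elements).  An RBF support-vector machine with fixed hyperparameters,
standardized on training statistics only, separates the classes; metrics
come from the confusion matrix.

Gray-level co-occurrence counting is delegated to
``skimage.feature.graycomatrix``; the 20 statistics are computed here
(only a handful exist in scikit-image) with log base 2 for the entropy
family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.metrics import confusion_matrix

__all__ = [
    "FEATURE_NAMES",
    "PatchFeatureRecord",
    "ConfusionMetrics",
    "augment",
    "patch16",
    "glcm",
    "features20",
    "build_dataset",
    "train_eval",
    "metrics_from_confusion",
]

GLCM_LEVELS = 8
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

FEATURE_NAMES = (
    "contrast",
    "dissimilarity",
    "homogeneity",
    "energy",
    "correlation",
    "entropy",
    "variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "autocorrelation",
    "cluster_shade",
    "cluster_prominence",
    "maximum_probability",
    "inverse_difference",
    "inverse_difference_moment",
)


@dataclass
class PatchFeatureRecord:
    """Provenance and 20 GLCM features for one augmented image patch."""

    region_id: str
    class_label: str
    augmentation: str  # orig / hflip / vflip
    patch_index: int  # 0..15 row-major
    parameter: str  # dop/dolp/docp/anisotropy or Mueller element name
    state: str  # input-state tag: H / P / V / R
    features: dict

    def __post_init__(self) -> None:
        if set(self.features) != set(FEATURE_NAMES):
            raise ValueError("record must carry exactly the 20 named features")
        if not all(np.isfinite(v) for v in self.features.values()):
            raise ValueError("all features must be finite")


@dataclass
class ConfusionMetrics:
    """Confusion counts and the derived percentage metrics.

    sensitivity = 100·tp/(tp+fn); precision = 100·tp/(tp+fp);
    specificity = 100·tn/(tn+fp); accuracy = 100·(tp+tn)/total;
    f1 = 100·2tp/(2tp+fp+fn).
    """

    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    precision: float
    specificity: float
    accuracy: float
    f1: float
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "sensitivity": self.sensitivity, "precision": self.precision,
            "specificity": self.specificity, "accuracy": self.accuracy,
            "f1": self.f1, "flags": list(self.flags),
        }


def metrics_from_confusion(tp: int, fn: int, fp: int, tn: int) -> ConfusionMetrics:
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be represented (tp+fn>0, tn+fp>0)")
    flags = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(f"undefined-{name}")
            return 0.0
        return 100.0 * num / den

    return ConfusionMetrics(
        tp=tp, fn=fn, fp=fp, tn=tn,
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        precision=ratio(tp, tp + fp, "precision"),
        specificity=ratio(tn, tn + fp, "specificity"),
        accuracy=ratio(tp + tn, tp + fn + fp + tn, "accuracy"),
        f1=ratio(2 * tp, 2 * tp + fp + fn, "f1"),
        flags=flags,
    )


def augment(image: np.ndarray) -> list:
    """[original, horizontal flip, vertical flip] of a 2D parameter image."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={img.ndim}")
    return [img, img[:, ::-1], img[::-1, :]]

AUGMENTATION_TAGS = ("orig", "hflip", "vflip")


def patch16(image: np.ndarray) -> list:
    """Cut an image into a 4×4 grid of 16 equal patches, row-major.

    Dimensions not divisible by 4 are center-cropped first.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={img.ndim}")
    h, w = img.shape
    if h < 4 or w < 4:
        raise ValueError(f"image must be at least 4x4, got {img.shape}")
    ch, cw = (h // 4) * 4, (w // 4) * 4
    top, left = (h - ch) // 2, (w - cw) // 2
    img = img[top : top + ch, left : left + cw]
    ph, pw = ch // 4, cw // 4
    return [
        img[i * ph : (i + 1) * ph, j * pw : (j + 1) * pw]
        for i in range(4)
        for j in range(4)
    ]


def quantize(patch: np.ndarray, value_range: tuple, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Uniform binning of a patch over its physical display range.

    Per-patch min/max scaling would erase the inter-patch contrast the
    classifier relies on, so the range is fixed per parameter.
    """
    lo, hi = value_range
    if hi <= lo:
        raise ValueError(f"invalid quantization range {value_range}")
    x = np.clip(np.asarray(patch, dtype=float), lo, hi)
    q = np.floor((x - lo) / (hi - lo) * levels).astype(np.uint8)
    return np.minimum(q, levels - 1)


def glcm(patch: np.ndarray, value_range: tuple = (0.0, 1.0),
         levels: int = GLCM_LEVELS, angles=GLCM_ANGLES) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix of a quantized patch,
    averaged over the unit-distance offsets; entries sum to 1."""
    q = quantize(patch, value_range, levels)
    p = graycomatrix(q, distances=[1], angles=list(angles),
                     levels=levels, symmetric=True, normed=True)
    return p[:, :, 0, :].mean(axis=-1)


def features20(g: np.ndarray) -> dict:
    """The 20 named texture statistics of one normalized GLCM.

    Level indices run 0..L−1; logs are base 2 with 0·log0 = 0.  A
    zero-variance (single-entry) GLCM gets correlation 0.  The
    inverse-difference pair uses the Clausi normalized forms so they stay
    distinct from homogeneity.
    """
    p = np.asarray(g, dtype=float)
    n = p.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())

    def xlog2(x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        nz = x > 0
        out[nz] = x[nz] * np.log2(x[nz])
        return out

    # p_{x+y}(k), k = 0..2n-2 and p_{x-y}(k), k = 0..n-1
    psum = np.zeros(2 * n - 1)
    np.add.at(psum, (i + j).ravel(), p.ravel())
    pdiff = np.zeros(n)
    np.add.at(pdiff, np.abs(i - j).ravel(), p.ravel())
    k_sum = np.arange(2 * n - 1)
    k_diff = np.arange(n)

    sum_average = float((k_sum * psum).sum())
    diff_average = float((k_diff * pdiff).sum())

    entropy = float(-xlog2(p).sum())
    hx = float(-xlog2(px).sum())
    hy = float(-xlog2(py).sum())
    pxpy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-(pxpy * log_pxpy).sum())

    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    if var_i > 0 and var_j > 0:
        correlation = float((((i - mu_i) * (j - mu_j) * p).sum())
                            / np.sqrt(var_i * var_j))
    else:
        correlation = 0.0

    return {
        "contrast": float(((i - j) ** 2 * p).sum()),
        "dissimilarity": float((np.abs(i - j) * p).sum()),
        "homogeneity": float((p / (1.0 + (i - j) ** 2)).sum()),
        "energy": float((p**2).sum()),
        "correlation": correlation,
        "entropy": entropy,
        "variance": var_i,
        "sum_average": sum_average,
        "sum_variance": float(((k_sum - sum_average) ** 2 * psum).sum()),
        "sum_entropy": float(-xlog2(psum).sum()),
        "difference_variance": float(((k_diff - diff_average) ** 2 * pdiff).sum()),
        "difference_entropy": float(-xlog2(pdiff).sum()),
        "imc1": float(imc1),
        "imc2": imc2,
        "autocorrelation": float((i * j * p).sum()),
        "cluster_shade": float(((i + j - mu_i - mu_j) ** 3 * p).sum()),
        "cluster_prominence": float(((i + j - mu_i - mu_j) ** 4 * p).sum()),
        "maximum_probability": float(p.max()),
        "inverse_difference": float((p / (1.0 + np.abs(i - j) / n)).sum()),
        "inverse_difference_moment": float((p / (1.0 + (i - j) ** 2 / n**2)).sum()),
    }


def build_dataset(region_images: list, parameter: str, state: str,
                  value_range: tuple = (0.0, 1.0)) -> pd.DataFrame:
    """Patch-feature table for one parameter/state combination.

    ``region_images`` is a list of (region_id, class_label, 2D image).
    Every region yields 3 augmentations × 16 patches, so 8 regions give
    the expected 384 records.
    """
    if not region_images:
        raise ValueError("no region images supplied")
    rows = []
    for region_id, class_label, image in region_images:
        if image is None:
            raise ValueError(f"missing image for region {region_id}")
        for tag, aug in zip(AUGMENTATION_TAGS, augment(np.asarray(image))):
            for idx, patch in enumerate(patch16(aug)):
                feats = features20(glcm(patch, value_range))
                rec = PatchFeatureRecord(
                    region_id=region_id,
                    class_label=class_label,
                    augmentation=tag,
                    patch_index=idx,
                    parameter=parameter,
                    state=state,
                    features=feats,
                )
                row = {
                    "region_id": rec.region_id,
                    "class_label": rec.class_label,
                    "augmentation": rec.augmentation,
                    "patch_index": rec.patch_index,
                    "parameter": rec.parameter,
                    "state": rec.state,
                }
                row.update(rec.features)
                rows.append(row)
    return pd.DataFrame(rows)


def _svm_pipeline(seed: int) -> Pipeline:
    # shared fixed hyperparameters: RBF kernel, C=1, gamma scaled by
    # feature count and variance; standardization fit on training data only
    return Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)),
    ])


def _confusion_to_metrics(y_true, y_pred) -> ConfusionMetrics:
    # "tumour" is the positive class
    cm = confusion_matrix(y_true, y_pred, labels=["normal", "tumour"])
    tn, fp, fn, tp = cm.ravel()
    return metrics_from_confusion(int(tp), int(fn), int(fp), int(tn))


def train_eval(table: pd.DataFrame, test_fraction: float = 0.2,
               seed: int = 0, split: str = "region") -> dict:
    """Train and evaluate the SVM on a patch-feature table.

    split="region" (default) holds out whole region images so augmented
    copies of one region never straddle train/test; split="patch" splits
    at the patch level (308/77-style) for comparison, at the cost of
    leakage between augmented copies.  Validation metrics come from
    5-fold cross-validation on the training portion; test metrics from
    the held-out portion.  Returns {"validation": ConfusionMetrics,
    "test": ConfusionMetrics}.
    """
    classes = table["class_label"].unique()
    if len(classes) < 2:
        raise ValueError("need at least two classes to train")
    feat_cols = list(FEATURE_NAMES)
    x = table[feat_cols].to_numpy()
    y = table["class_label"].to_numpy()

    if split == "region":
        regions = table[["region_id", "class_label"]].drop_duplicates()
        train_r, test_r = train_test_split(
            regions["region_id"].to_numpy(),
            test_size=test_fraction,
            stratify=regions["class_label"].to_numpy(),
            random_state=seed,
        )
        train_mask = table["region_id"].isin(train_r).to_numpy()
    elif split == "patch":
        idx_train, _ = train_test_split(
            np.arange(len(table)),
            test_size=test_fraction,
            stratify=y,
            random_state=seed,
        )
        train_mask = np.zeros(len(table), dtype=bool)
        train_mask[idx_train] = True
    else:
        raise ValueError(f"unknown split policy {split!r}")

    x_train, y_train = x[train_mask], y[train_mask]
    x_test, y_test = x[~train_mask], y[~train_mask]

    pipe = _svm_pipeline(seed)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    y_val_pred = cross_val_predict(pipe, x_train, y_train, cv=cv)
    validation = _confusion_to_metrics(y_train, y_val_pred)

    pipe.fit(x_train, y_train)
    test = _confusion_to_metrics(y_test, pipe.predict(x_test))
    return {"validation": validation, "test": test}
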