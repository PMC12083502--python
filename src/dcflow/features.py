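"""The 12 rBFI image features and PCA reduction.

Eight of the features summarize the first-order pixel distribution of the
16 x 16 rBFI slice (maximum, minimum, variance, coefficient of variation,
range, skewness, interquartile range, histogram entropy), two are
second-order Haralick texture statistics from a gray-level co-occurrence
matrix (contrast and energy), and two segment the high-flow region at the
half-height level between image minimum and maximum (the FWHM threshold and
the mean of pixels above it).  Malignant-like flow maps — higher magnitude
and heterogeneity — push the spread, texture, and high-flow features up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix, graycoprops
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = ["FEATURE_NAMES", "FeatureVector", "compute_features", "pca_reduce",
           "features_to_frame"]

FEATURE_NAMES = (
    "maximum",
    "minimum",
    "variance",
    "coefficient_of_variation",
    "range",
    "skewness",
    "interquartile_range",
    "textural_contrast",
    "textural_energy",
    "entropy",
    "fwhm_threshold",
    "mean_above_fwhm",
)

N_GRAY_LEVELS = 16  # min-max quantization depth for GLCM and histogram


@dataclass(frozen=True)
class FeatureVector:
    maximum: float
    minimum: float
    variance: float
    coefficient_of_variation: float
    range: float
    skewness: float
    interquartile_range: float
    textural_contrast: float
    textural_energy: float
    entropy: float
    fwhm_threshold: float
    mean_above_fwhm: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


def _quantize(img: np.ndarray, levels: int = N_GRAY_LEVELS) -> np.ndarray:
    """Min-max quantization to integer gray levels 0..levels-1."""
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def compute_features(img: np.ndarray) -> FeatureVector:
    """Compute the 12 features of a 2-D nonnegative flow image.

    Variance and the coefficient of variation use population moments;
    skewness is the Fisher-Pearson moment coefficient (0 for a constant
    image); quartiles interpolate linearly.  The GLCM uses 16 min-max gray
    levels, unit offset, symmetric counts averaged over the four principal
    directions; texture energy is the angular second moment.  Entropy is the
    base-2 Shannon entropy of the 16-bin min-max histogram.
    """
    img = np.asarray(img, dtype=float)
    if img.size < 4:
        raise ValueError("image must have at least 4 pixels")
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    if np.any(img < 0):
        raise ValueError("flow image must be nonnegative")

    flat = img.ravel()
    vmax, vmin = float(flat.max()), float(flat.min())
    mean = float(flat.mean())
    var = float(flat.var())  # population variance
    std = np.sqrt(var)
    # a numerically constant image has zero spread features (guard the
    # floating-point residual of var() on constant input)
    tiny = 1e-12 * max(abs(mean), 1.0)
    cv = std / mean if (mean > 0 and std > tiny) else 0.0
    if std > tiny:
        skew = float(np.mean((flat - mean) ** 3) / std**3)
    else:
        skew = 0.0
    q1, q3 = np.percentile(flat, [25, 75])
    iqr = float(q3 - q1)

    q = _quantize(img)
    glcm = graycomatrix(
        q,
        distances=[1],
        angles=[0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=N_GRAY_LEVELS,
        symmetric=True,
        normed=True,
    )
    contrast = float(graycoprops(glcm, "contrast").mean())
    energy = float(graycoprops(glcm, "ASM").mean())

    counts = np.bincount(q.ravel(), minlength=N_GRAY_LEVELS).astype(float)
    p = counts / counts.sum()
    p = p[p > 0]
    ent = float(-(p * np.log2(p)).sum())

    fwhm = vmin + (vmax - vmin) / 2.0
    above = flat[flat > fwhm]
    mean_above = float(above.mean()) if above.size else fwhm

    return FeatureVector(
        maximum=vmax,
        minimum=vmin,
        variance=var,
        coefficient_of_variation=float(cv),
        range=vmax - vmin,
        skewness=skew,
        interquartile_range=iqr,
        textural_contrast=contrast,
        textural_energy=energy,
        entropy=ent,
        fwhm_threshold=float(fwhm),
        mean_above_fwhm=mean_above,
    )


def features_to_frame(
    vectors, labels=None, ids=None
) -> pd.DataFrame:
    """Stack FeatureVectors into a table with optional id/label columns."""
    rows = np.vstack([v.as_array() for v in vectors])
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if ids is not None:
        df.insert(0, "id", list(ids))
    if labels is not None:
        df["label"] = list(labels)
    return df


def pca_reduce(
    train_features: np.ndarray | pd.DataFrame,
    test_features: np.ndarray | pd.DataFrame | None = None,
    k: int = 2,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Project standardized features onto the top-k principal components.

    Components are fitted on the training table only (after z-scoring by
    training statistics); both tables are projected.  A rank-deficient
    training table yields fewer components with a warning.
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D feature table")
    if k > X.shape[1]:
        raise ValueError("k cannot exceed the number of features")
    if X.shape[0] < k:
        raise ValueError("need at least k training rows")
    scaler = StandardScaler().fit(X)
    # guard constant columns
    scaler.scale_[scaler.scale_ == 0] = 1.0
    Xs = scaler.transform(X)
    rank = np.linalg.matrix_rank(Xs - Xs.mean(axis=0))
    n_comp = min(k, max(rank, 1))
    if n_comp < k:
        warnings.warn(f"training table rank {rank} < k={k}; using {n_comp} components")
    pca = PCA(n_components=n_comp, svd_solver="full").fit(Xs)
    out_train = pca.transform(Xs)
    out_test = None
    if test_features is not None:
        out_test = pca.transform(scaler.transform(np.asarray(test_features, dtype=float)))
    return out_train, out_test
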