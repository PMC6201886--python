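"""Classical focus-quality baseline.

The comparison method: tiles are downsampled to 20x (200x200 px in the
original protocol), described by the Tenengrad focus measure plus Haralick
statistics of the gray-level co-occurrence matrix (GLCM), classified by a
decision tree, and the resulting label map is cleaned up by gray-scale
morphological closing followed by opening with a 3x3 structuring element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import graycomatrix
from sklearn.tree import DecisionTreeClassifier

GLCM_LEVELS = 32
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
FEATURE_COLUMNS = ("tenengrad", "glcm_contrast", "glcm_entropy",
                   "glcm_energy", "glcm_homogeneity")


def to_gray(tile: np.ndarray) -> np.ndarray:
    """Luminance conversion (0.299 R + 0.587 G + 0.114 B) for RGB input;
    single-channel input passes through."""
    tile = np.asarray(tile, dtype=float)
    if tile.ndim == 2:
        return tile
    if tile.ndim == 3 and tile.shape[-1] == 3:
        return tile @ np.array([0.299, 0.587, 0.114])
    raise ValueError("expected a 2-D gray or (h, w, 3) RGB tile")


def downsample_to_20x(tile_40x: np.ndarray) -> np.ndarray:
    """2x area-average downsampling (40x -> 20x magnification)."""
    tile = np.asarray(tile_40x, dtype=float)
    h, w = tile.shape[:2]
    if h % 2 or w % 2:
        raise ValueError("tile sides must be even for 2x downsampling")
    if tile.ndim == 2:
        return tile.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
    return tile.reshape(h // 2, 2, w // 2, 2, tile.shape[-1]).mean(axis=(1, 3))


def tenengrad(gray: np.ndarray) -> float:
    """Mean squared 3x3 Sobel gradient magnitude (reflect boundary).

    A standard sharpness measure: decreases monotonically with defocus.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ValueError("tenengrad expects a single-channel tile")
    gx = ndimage.sobel(gray, axis=1, mode="reflect")
    gy = ndimage.sobel(gray, axis=0, mode="reflect")
    return float(np.mean(gx * gx + gy * gy))


def quantize(gray: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Uniform quantization of a [0, 1] gray tile to integer levels."""
    g = np.clip(np.asarray(gray, dtype=float), 0.0, 1.0)
    return np.minimum((g * levels).astype(np.uint8), levels - 1)


def glcm(
    gray: np.ndarray,
    levels: int = GLCM_LEVELS,
    distance: int = 1,
    angles=GLCM_ANGLES,
) -> np.ndarray:
    """Normalized symmetric gray-level co-occurrence matrix.

    Pairs at the given pixel distance are counted in both directions for
    each angle; the per-angle matrices are averaged and the result sums
    to 1.  Input may be a [0, 1] float tile (quantized here) or an
    already-quantized integer tile.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    gray = np.asarray(gray)
    q = gray if np.issubdtype(gray.dtype, np.integer) else quantize(gray, levels)
    if q.max() >= levels:
        raise ValueError("quantized input exceeds the stated number of levels")
    mats = graycomatrix(
        q, distances=[distance], angles=list(angles), levels=levels, symmetric=True
    )[:, :, 0, :].astype(float)
    counts = mats.sum(axis=-1)  # aggregate over angles
    total = counts.sum()
    if total == 0:
        raise ValueError("tile too small for the requested pair distance")
    return counts / total


def haralick_features(p: np.ndarray) -> dict[str, float]:
    """Scalar texture statistics of a normalized GLCM.

    contrast = sum p(i,j) (i-j)^2; entropy = -sum p log2 p (0 log 0 := 0);
    plus energy and homogeneity as optional extras.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("expected a square co-occurrence matrix")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("co-occurrence matrix must be normalized (sum to 1)")
    i, j = np.indices(p.shape)
    nz = p > 0
    return {
        "contrast": float((p * (i - j) ** 2).sum()),
        "entropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "energy": float((p * p).sum()),
        "homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
    }


def focus_features(tile_40x: np.ndarray, downsample: bool = True) -> dict[str, float]:
    """The baseline's feature vector for one RGB (or gray) tile."""
    gray = to_gray(tile_40x)
    if downsample:
        gray = downsample_to_20x(gray)
    h = haralick_features(glcm(gray))
    return {
        "tenengrad": tenengrad(gray),
        "glcm_contrast": h["contrast"],
        "glcm_entropy": h["entropy"],
        "glcm_energy": h["energy"],
        "glcm_homogeneity": h["homogeneity"],
    }


def feature_table(tiles: np.ndarray, downsample: bool = True) -> pd.DataFrame:
    """Feature vectors for a stack of tiles -> DataFrame with
    ``FEATURE_COLUMNS``."""
    rows = [focus_features(t, downsample=downsample) for t in tiles]
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def fit_tree(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    max_depth: int = 8,
    seed: int = 0,
) -> DecisionTreeClassifier:
    """CART decision tree (Gini impurity) on focus features."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    tree = DecisionTreeClassifier(max_depth=max_depth, criterion="gini", random_state=seed)
    tree.fit(np.asarray(features, dtype=float), labels)
    return tree


def predict_tree(tree: DecisionTreeClassifier, features) -> np.ndarray:
    return tree.predict(np.asarray(features, dtype=float))


def morphological_cleanup(mask: np.ndarray) -> np.ndarray:
    """Gray-scale morphological closing then opening, 3x3 square
    structuring element, reflect boundary.  Removes isolated
    false-positive tiles and fills isolated holes in the label map."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("expected a 2-D label/probability grid")
    closed = ndimage.grey_erosion(
        ndimage.grey_dilation(mask, size=(3, 3), mode="reflect"),
        size=(3, 3), mode="reflect",
    )
    opened = ndimage.grey_dilation(
        ndimage.grey_erosion(closed, size=(3, 3), mode="reflect"),
        size=(3, 3), mode="reflect",
    )
    return opened


@dataclass
class BaselineClassifier:
    """Fitted baseline pipeline: feature extraction + decision tree."""

    tree: DecisionTreeClassifier
    downsample: bool = True

    @classmethod
    def fit(cls, tiles: np.ndarray, labels: np.ndarray, max_depth: int = 8,
            seed: int = 0, downsample: bool = True) -> "BaselineClassifier":
        feats = feature_table(tiles, downsample=downsample)
        return cls(tree=fit_tree(feats, labels, max_depth=max_depth, seed=seed),
                   downsample=downsample)

    def predict(self, tiles: np.ndarray) -> np.ndarray:
        feats = feature_table(tiles, downsample=self.downsample)
        return predict_tree(self.tree, feats)
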