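"""Dataset assembly and preprocessing for tile classification.

Intensity scaling to [0, 1], per-channel zero-centering with training-split
statistics only, dihedral (flip / 90-degree rotation) augmentation, class
balancing by downsampling, and stratified validation splitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blurlab import LABEL_BLURRED, LABEL_IN_FOCUS

LABELS = (LABEL_IN_FOCUS, LABEL_BLURRED)


@dataclass
class TileDataset:
    """An ordered tile collection: a manifest (one row per tile) and,
    optionally, the rendered pixels aligned row-for-row.

    ``pixels`` may be None for bookkeeping at full protocol scale, where
    only labels and provenance matter.
    """

    manifest: pd.DataFrame
    pixels: np.ndarray | None = None
    split_tag: str = "unsplit"

    def __post_init__(self) -> None:
        if self.pixels is not None and len(self.pixels) != len(self.manifest):
            raise ValueError("pixels and manifest must have equal length")

    def __len__(self) -> int:
        return len(self.manifest)

    @property
    def labels(self) -> np.ndarray:
        return self.manifest["label"].to_numpy()

    @property
    def class_counts(self) -> dict[str, int]:
        vc = self.manifest["label"].value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in LABELS}

    def take(self, idx: np.ndarray, split_tag: str | None = None) -> "TileDataset":
        return TileDataset(
            manifest=self.manifest.iloc[idx].reset_index(drop=True),
            pixels=None if self.pixels is None else self.pixels[idx],
            split_tag=split_tag or self.split_tag,
        )


@dataclass(frozen=True)
class PreprocessStats:
    """Per-channel means computed on the training split before centering.

    Stored with any trained model so that new data is centred with the
    same statistics (no leakage, idempotent in the stats)."""

    channel_means: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {"channel_means": [float(m) for m in self.channel_means]}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessStats":
        return cls(channel_means=tuple(float(m) for m in d["channel_means"]))


def scale_intensities(raw_tile: np.ndarray) -> np.ndarray:
    """Linearly scale 8-bit colour intensities to [0, 1] (divide by 255).

    Refuses float input already in [0, 1] — scaling twice would silently
    shrink the data range.
    """
    raw_tile = np.asarray(raw_tile)
    if raw_tile.ndim < 2:
        raise ValueError("expected an image array")
    if np.issubdtype(raw_tile.dtype, np.floating):
        if raw_tile.size and raw_tile.max() <= 1.0:
            raise ValueError("input already scaled to [0, 1]; refusing to rescale")
        if not np.allclose(raw_tile, np.round(raw_tile)):
            raise ValueError("expected integer-valued 8-bit input")
    if raw_tile.size and (raw_tile.min() < 0 or raw_tile.max() > 255):
        raise ValueError("8-bit input must lie in [0, 255]")
    return (raw_tile / 255.0).astype(np.float32)


def compute_channel_means(pixels: np.ndarray) -> PreprocessStats:
    """Per-channel mean over an (n, h, w, 3) stack of [0, 1] tiles."""
    if pixels.ndim != 4 or pixels.shape[-1] != 3:
        raise ValueError("expected (n, h, w, 3) pixel stack")
    if len(pixels) == 0:
        raise ValueError("empty dataset")
    means = pixels.mean(axis=(0, 1, 2), dtype=np.float64)
    return PreprocessStats(channel_means=tuple(float(m) for m in means))


def apply_stats(pixels: np.ndarray, stats: PreprocessStats) -> np.ndarray:
    """Subtract stored per-channel means (does not recompute them)."""
    return (pixels - np.asarray(stats.channel_means, dtype=np.float32)).astype(np.float32)


def zero_center(
    train: TileDataset, *others: TileDataset
) -> tuple[tuple[TileDataset, ...], PreprocessStats]:
    """Zero-centre datasets using the training split's channel means.

    Returns the centred datasets (train first, then the others, e.g. a
    validation split — centred with the *training* means, so their own
    post-centering means need not vanish) and the stats to store with a
    trained model.
    """
    if train.pixels is None or len(train) == 0:
        raise ValueError("training dataset with pixels required")
    stats = compute_channel_means(train.pixels)
    out = []
    for ds in (train, *others):
        if ds.pixels is None:
            raise ValueError("cannot centre a dataset without pixels")
        out.append(TileDataset(ds.manifest, apply_stats(ds.pixels, stats), ds.split_tag))
    return tuple(out), stats


# ---------------------------------------------------------------------------
# augmentation

#: The 8 dihedral transforms reachable from {identity, h-flip, v-flip} x
#: {0, 90-degree rotation}.
_DIHEDRAL = [
    lambda t: t,
    lambda t: t[:, ::-1],
    lambda t: t[::-1, :],
    lambda t: t[::-1, ::-1],
    lambda t: np.rot90(t),
    lambda t: np.rot90(t)[:, ::-1],
    lambda t: np.rot90(t)[::-1, :],
    lambda t: np.rot90(t)[::-1, ::-1],
]


def augment(tile: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random dihedral transform (flips and/or a 90-degree rotation).

    Labels, offsets and the pixel multiset are untouched by construction.
    """
    tile = np.asarray(tile)
    if tile.shape[0] != tile.shape[1]:
        raise ValueError("augmentation requires a square tile")
    k = int(rng.integers(0, 8))
    return np.ascontiguousarray(_DIHEDRAL[k](tile))


def augment_batch(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently augment every tile in an (n, h, w, c) batch."""
    return np.stack([augment(t, rng) for t in batch])


# ---------------------------------------------------------------------------
# balancing and splitting


def balance_classes(
    dataset: TileDataset, n_per_class: int, rng: np.random.Generator
) -> TileDataset:
    """Randomly downsample (without replacement) to ``n_per_class`` tiles
    per class, preventing class imbalance during training."""
    idx_parts = []
    labels = dataset.labels
    for lab in LABELS:
        idx = np.flatnonzero(labels == lab)
        if len(idx) < n_per_class:
            raise ValueError(
                f"class '{lab}' has only {len(idx)} tiles; cannot sample {n_per_class}"
            )
        idx_parts.append(rng.choice(idx, size=n_per_class, replace=False))
    keep = np.sort(np.concatenate(idx_parts))
    return dataset.take(keep)


def split_validation(
    dataset: TileDataset, fraction: float, rng: np.random.Generator
) -> tuple[TileDataset, TileDataset]:
    """Hold out ``round(fraction * n)`` tiles as validation, stratified by
    class (class proportions preserved within one tile); disjoint and
    exhaustive."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(dataset)
    n_val = int(round(fraction * n))
    labels = dataset.labels
    val_parts = []
    # largest-remainder apportionment of the validation quota over classes
    class_idx = {lab: np.flatnonzero(labels == lab) for lab in LABELS if (labels == lab).any()}
    quotas = {lab: fraction * len(idx) for lab, idx in class_idx.items()}
    base = {lab: int(np.floor(q)) for lab, q in quotas.items()}
    rem = n_val - sum(base.values())
    order = sorted(class_idx, key=lambda lab: quotas[lab] - base[lab], reverse=True)
    for lab in order[:rem]:
        base[lab] += 1
    for lab, idx in class_idx.items():
        take = rng.choice(idx, size=base[lab], replace=False)
        val_parts.append(take)
    val_idx = np.sort(np.concatenate(val_parts)) if val_parts else np.array([], dtype=int)
    mask = np.zeros(n, dtype=bool)
    mask[val_idx] = True
    train = dataset.take(np.flatnonzero(~mask), split_tag="train")
    val = dataset.take(val_idx, split_tag="validation")
    return train, val
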