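"""Shared fixtures: small rendered datasets and a quickly trained compact
model for pipeline tests."""

from __future__ import annotations

import numpy as np
import pytest

from deepfocus import blurlab, focusnet, tileset

#: Compact topology for fast unit-test training runs.
TINY_SPEC = focusnet.ArchitectureSpec(
    conv_channels=(4, 8, 8, 16, 16),
    conv_kernels=(5, 3, 3, 3, 3),
    fc_layers=(32,),
)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def textured_tile():
    """One sharp rendered H&E-like tile with visible structure."""
    return blurlab.render_sharp_tile(blurlab.SyntheticTileSpec(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """2 slides x 9 offsets x 12 positions = 216 rendered tiles."""
    pixels, manifest = blurlab.generate_dataset(2, tiles_per_roi=12, seed=7)
    return tileset.TileDataset(manifest, pixels)


def prepare_splits(dataset, seed=0, fraction=0.1):
    """Balance, split and centre a dataset; returns (train, val, stats)."""
    rng = np.random.default_rng(seed)
    balanced = tileset.balance_classes(dataset, min(dataset.class_counts.values()), rng)
    train, val = tileset.split_validation(balanced, fraction, rng)
    (train_c, val_c), stats = tileset.zero_center(train, val)
    return train_c, val_c, stats


@pytest.fixture(scope="session")
def tiny_trained():
    """A compact model trained briefly on an easy blur-vs-sharp problem.

    Returns (model, stats, history); accurate enough to separate
    strongly blurred from in-focus tiles.
    """
    pixels, manifest = blurlab.generate_dataset(
        3, offsets=(-2.5, 0.0, 2.5), tiles_per_roi=40, seed=5
    )
    ds = tileset.TileDataset(manifest, pixels)
    train_c, val_c, stats = prepare_splits(ds)
    model = focusnet.build_model(TINY_SPEC, rng_seed=0)
    model, history = focusnet.train(
        model, train_c, val_c, focusnet.TrainingConfig(max_epochs=4, seed=0)
    )
    model.preprocess_stats = stats
    return model, stats, history
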