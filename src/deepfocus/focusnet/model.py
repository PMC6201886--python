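"""The tile-focus classifier network.

Topology: five stride-1 'same' convolutions, each followed by ReLU then
batch normalization (BN after the activation), with 2x2 max pooling after
the third, fourth and fifth conv blocks (64 -> 32 -> 16 -> 8 px); then
fully connected ReLU layers with dropout, and a softmax over the two
classes (blurred / in-focus).  The objective during training is the
categorical cross-entropy between label and prediction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..blurlab import LABEL_BLURRED, LABEL_IN_FOCUS, TILE_SIZE
from ..tileset import PreprocessStats
from . import layers as L

#: Class index convention: column 0 = blurred, column 1 = in-focus.
CLASS_ORDER = (LABEL_BLURRED, LABEL_IN_FOCUS)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Network topology.

    Exactly five conv layers with pooling after conv 3, 4 and 5 (the
    checked invariant of this architecture family).  Channel and FC widths
    are configurable; the defaults are sized for single-CPU training of
    the pure-NumPy engine.  Kernel defaults: 5x5 for layer 1, 3x3 for the
    rest (the grid-search optimum for the first two layers).
    """

    conv_channels: tuple[int, ...] = (8, 16, 16, 32, 32)
    conv_kernels: tuple[int, ...] = (5, 3, 3, 3, 3)
    pool_after: tuple[int, ...] = (3, 4, 5)  # 1-based conv indices
    fc_layers: tuple[int, ...] = (64, 32)
    n_classes: int = 2
    bn_eps: float = L.DEFAULT_BN_EPS
    bn_momentum: float = L.DEFAULT_BN_MOMENTUM

    def __post_init__(self):
        if len(self.conv_channels) != 5 or len(self.conv_kernels) != 5:
            raise ValueError("architecture requires exactly 5 conv layers")
        if tuple(self.pool_after) != (3, 4, 5):
            raise ValueError("pooling must follow conv layers 3, 4 and 5")
        if self.n_classes != 2:
            raise ValueError("this is a two-class (in-focus/blurred) architecture")


class FocusNet:
    """A built network: ordered layers plus the preprocessing statistics
    it expects its input to be centred with."""

    def __init__(self, spec: ArchitectureSpec, dropout_p: float = 0.2, seed: int = 0):
        self.spec = spec
        self.dropout_p = dropout_p
        self.seed = seed
        self.preprocess_stats: PreprocessStats | None = None
        rng = np.random.default_rng(seed)
        net: list[L.Layer] = []
        c_in = 3
        for i, (c_out, k) in enumerate(zip(spec.conv_channels, spec.conv_kernels), start=1):
            net.append(L.Conv2D(c_in, c_out, k, rng, compute_input_grad=(i > 1)))
            net.append(L.ReLU())
            net.append(L.BatchNorm(c_out, spec.bn_eps, spec.bn_momentum))
            if i in spec.pool_after:
                net.append(L.MaxPool2())
            c_in = c_out
        net.append(L.Flatten())
        side = TILE_SIZE // 2 ** len(spec.pool_after)
        n_in = side * side * spec.conv_channels[-1]
        for width in spec.fc_layers:
            net.append(L.Dense(n_in, width, rng))
            net.append(L.ReLU())
            net.append(L.Dropout(dropout_p))
            n_in = width
        net.append(L.Dense(n_in, spec.n_classes, rng))
        self.layers = net

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, mode: str = "infer", rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, mode=mode, rng=rng)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dlogits = layer.backward(dlogits)
        return dlogits

    def sgd_step(self, lr: float) -> None:
        for layer in self.layers:
            for name, p in layer.params.items():
                p -= lr * layer.grads[name]

    # -- parameter bookkeeping --------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learnable parameters plus BN running statistics, keyed
        ``layer{i}.{name}``."""
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                out[f"layer{i}.{name}"] = p
            if isinstance(layer, L.BatchNorm):
                out[f"layer{i}.running_mean"] = layer.state.running_mean
                out[f"layer{i}.running_var"] = layer.state.running_var
                out[f"layer{i}.bn_updates"] = layer.state.n_updates
        return out

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        arrays = self.state_arrays()
        if set(state) != set(arrays):
            raise ValueError("parameter name mismatch when restoring model state")
        for k, v in arrays.items():
            v[:] = state[k]

    # -- inference ---------------------------------------------------------

    def predict_proba(self, tiles: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Probability of each tile being in focus.

        Expects zero-centred float tiles (n, 64, 64, 3); raw 8-bit or
        un-centred [0, 1] input is rejected.  Batch-order independent
        (inference-mode BN, no dropout).
        """
        tiles = np.asarray(tiles)
        if tiles.ndim == 3:
            tiles = tiles[None]
        if tiles.shape[1:] != (TILE_SIZE, TILE_SIZE, 3):
            raise ValueError(f"expected (n, {TILE_SIZE}, {TILE_SIZE}, 3) tiles")
        if not np.issubdtype(tiles.dtype, np.floating):
            raise ValueError("tiles must be float and preprocessed (scaled + centred)")
        looks_uncentred = tiles.size and tiles.min() >= 0.0 and tiles.max() > 0.5
        if tiles.size and (tiles.min() < -1.5 or tiles.max() > 1.5 or looks_uncentred):
            raise ValueError(
                "tiles do not look zero-centred; apply the model's PreprocessStats first"
            )
        out = np.empty(len(tiles), dtype=np.float64)
        for start in range(0, len(tiles), batch_size):
            batch = tiles[start:start + batch_size].astype(np.float32)
            probs = L.softmax(self.forward(batch, mode="infer"))
            out[start:start + batch_size] = probs[:, CLASS_ORDER.index(LABEL_IN_FOCUS)]
        return out


def build_model(
    spec: ArchitectureSpec | None = None, rng_seed: int = 0, dropout_p: float = 0.2
) -> FocusNet:
    """Construct a network with deterministic (He) initialization."""
    return FocusNet(spec or ArchitectureSpec(), dropout_p=dropout_p, seed=rng_seed)


def classify(p_in_focus) -> np.ndarray | str:
    """Threshold the in-focus probability: in-focus iff p > 0.5 (strict)."""
    p = np.asarray(p_in_focus, dtype=float)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    out = np.where(p > 0.5, LABEL_IN_FOCUS, LABEL_BLURRED)
    return out.item() if np.isscalar(p_in_focus) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# checkpointing

_FORMAT_VERSION = 1


def save_model(model: FocusNet, path: str | Path) -> Path:
    """Write a checkpoint directory: weights.npz + meta.json (architecture,
    dropout, preprocessing statistics, weight checksum)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    weights_file = path / "weights.npz"
    np.savez(weights_file, **model.state_arrays())
    digest = hashlib.sha256(weights_file.read_bytes()).hexdigest()
    if model.preprocess_stats is None:
        raise ValueError("model has no PreprocessStats; refusing to save an unusable checkpoint")
    meta = {
        "format_version": _FORMAT_VERSION,
        "architecture": asdict(model.spec),
        "dropout_p": model.dropout_p,
        "seed": model.seed,
        "preprocess_stats": model.preprocess_stats.to_dict(),
        "weights_sha256": digest,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    return path


def load_model(path: str | Path) -> FocusNet:
    """Load a checkpoint; verifies format version, checksum and the
    presence of preprocessing statistics."""
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise FileNotFoundError(f"no checkpoint metadata at {meta_file}")
    meta = json.loads(meta_file.read_text())
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"checkpoint format version {meta.get('format_version')} not supported "
            f"(expected {_FORMAT_VERSION})"
        )
    if "preprocess_stats" not in meta or meta["preprocess_stats"] is None:
        raise ValueError("checkpoint lacks PreprocessStats; cannot classify raw tiles")
    weights_file = path / "weights.npz"
    digest = hashlib.sha256(weights_file.read_bytes()).hexdigest()
    if digest != meta["weights_sha256"]:
        raise ValueError("checkpoint weights failed checksum verification")
    arch = meta["architecture"]
    spec = ArchitectureSpec(
        conv_channels=tuple(arch["conv_channels"]),
        conv_kernels=tuple(arch["conv_kernels"]),
        pool_after=tuple(arch["pool_after"]),
        fc_layers=tuple(arch["fc_layers"]),
        n_classes=arch["n_classes"],
        bn_eps=arch["bn_eps"],
        bn_momentum=arch["bn_momentum"],
    )
    model = FocusNet(spec, dropout_p=meta["dropout_p"], seed=meta["seed"])
    with np.load(weights_file) as npz:
        model.set_state({k: npz[k] for k in npz.files})
    model.preprocess_stats = PreprocessStats.from_dict(meta["preprocess_stats"])
    return model
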