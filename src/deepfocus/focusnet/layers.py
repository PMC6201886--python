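"""Minimal NumPy neural-network layers with manual backprop.

Just enough machinery for a small tile classifier: stride-1 'same'
convolution (im2col + BLAS matmul), ReLU, batch normalization with
running inference statistics, 2x2 max pooling, dense layers, inverted
dropout and a fused softmax/cross-entropy head.  All tensors are NHWC
float32.  Every layer exposes ``forward(x, mode, rng)`` / ``backward(dy)``
and dicts of parameters and gradients keyed by name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_BN_EPS = float(np.exp(-15.0))  # e^-15 ~ 3.06e-7
DEFAULT_BN_MOMENTUM = 0.99


class Layer:
    """Base layer: stateless unless it declares params."""

    def forward(self, x: np.ndarray, mode: str = "infer", rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {}

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return {}


def _im2col(x_pad: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, Hp, Wp, C) -> (N*H*W, kh*kw*C) patch matrix (stride 1)."""
    n, hp, wp, c = x_pad.shape
    h, w = hp - kh + 1, wp - kw + 1
    win = np.lib.stride_tricks.sliding_window_view(x_pad, (kh, kw), axis=(1, 2))
    # win: (N, H, W, C, kh, kw) -> (N, H, W, kh, kw, C)
    win = win.transpose(0, 1, 2, 4, 5, 3)
    return np.ascontiguousarray(win).reshape(n * h * w, kh * kw * c)


class Conv2D(Layer):
    """Stride-1 convolution with symmetric 'same' padding (odd kernels).

    Weights (kh, kw, c_in, c_out), He-initialized.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 compute_input_grad: bool = True):
        if kernel % 2 == 0 or kernel < 1:
            raise ValueError("kernel size must be odd and positive")
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        # the first layer of a network has no upstream layer to feed, so
        # its (expensive) input gradient can be skipped
        self.compute_input_grad = compute_input_grad
        fan_in = kernel * kernel * c_in
        self.W = (rng.standard_normal((kernel, kernel, c_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._x_shape = None

    def forward(self, x, mode="infer", rng=None):
        k, p = self.kernel, self.kernel // 2
        n, h, w, _ = x.shape
        x_pad = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = _im2col(x_pad, k, k)
        y = cols @ self.W.reshape(-1, self.c_out) + self.b
        if mode == "train":
            self._cols, self._x_shape = cols, x.shape
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy):
        n, h, w, _ = self._x_shape
        k, p = self.kernel, self.kernel // 2
        dy_flat = dy.reshape(-1, self.c_out)
        self.dW[:] = (self._cols.T @ dy_flat).reshape(self.W.shape)
        self.db[:] = dy_flat.sum(axis=0)
        self._cols = None
        if not self.compute_input_grad:
            return None
        # dX = 'same' convolution of dy with the spatially flipped kernel,
        # in/out channels transposed (valid because padding is symmetric).
        w_rot = self.W[::-1, ::-1].transpose(0, 1, 3, 2).reshape(-1, self.c_in)
        dy_pad = np.pad(dy, ((0, 0), (p, p), (p, p), (0, 0)))
        dx = _im2col(dy_pad, k, k) @ w_rot
        return dx.reshape(n, h, w, self.c_in)

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def grads(self):
        return {"W": self.dW, "b": self.db}


class ReLU(Layer):
    def forward(self, x, mode="infer", rng=None):
        y = np.maximum(x, 0.0)
        if mode == "train":
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


@dataclass
class BatchNormState:
    """Per-feature batch-normalization state.

    Training normalizes each feature by the mini-batch mean and
    *population* variance, then applies the learned affine (gamma, beta);
    inference uses the exponentially averaged running statistics.
    """

    gamma: np.ndarray
    beta: np.ndarray
    eps: float = DEFAULT_BN_EPS
    momentum: float = DEFAULT_BN_MOMENTUM
    running_mean: np.ndarray = None
    running_var: np.ndarray = None
    n_updates: np.ndarray = None  # 1-element counter, for EMA bias correction

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.running_mean is None:
            self.running_mean = np.zeros_like(self.gamma)
        if self.running_var is None:
            self.running_var = np.zeros_like(self.gamma)
        if self.n_updates is None:
            self.n_updates = np.zeros(1, dtype=np.int64)

    def inference_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """Bias-corrected running mean/variance (EMA divided by 1 - m^t,
        so short training runs are not dominated by the zero init)."""
        t = int(self.n_updates[0])
        if t == 0:
            return np.zeros_like(self.gamma), np.ones_like(self.gamma)
        corr = 1.0 - self.momentum**t
        return self.running_mean / corr, self.running_var / corr

    @classmethod
    def create(cls, n_features: int, eps: float = DEFAULT_BN_EPS,
               momentum: float = DEFAULT_BN_MOMENTUM) -> "BatchNormState":
        return cls(
            gamma=np.ones(n_features, dtype=np.float32),
            beta=np.zeros(n_features, dtype=np.float32),
            eps=eps,
            momentum=momentum,
        )


def batch_norm_forward(u: np.ndarray, state: BatchNormState, mode: str = "train"):
    """Normalize a (batch, features) array:  u_hat = (u - mean) / sqrt(var + eps),
    then gamma * u_hat + beta.

    Train mode computes mini-batch statistics (population variance,
    batch >= 2 required) and updates the running statistics in place;
    infer mode uses the running statistics.  Returns (output, cache);
    the cache feeds :func:`batch_norm_backward`.
    """
    if mode == "train":
        if u.shape[0] < 2:
            raise ValueError("batch normalization in train mode requires batch size >= 2")
        mean = u.mean(axis=0)
        var = u.var(axis=0)  # population (ddof=0)
        m = state.momentum
        state.running_mean[:] = m * state.running_mean + (1 - m) * mean
        state.running_var[:] = m * state.running_var + (1 - m) * var
        state.n_updates += 1
    else:
        mean, var = state.inference_stats()
    inv_std = 1.0 / np.sqrt(var + state.eps)
    u_hat = (u - mean) * inv_std
    out = state.gamma * u_hat + state.beta
    return out, (u_hat, inv_std)


def batch_norm_backward(dy: np.ndarray, state: BatchNormState, cache):
    """Gradients of the batch-norm transform wrt input, gamma and beta."""
    u_hat, inv_std = cache
    n = dy.shape[0]
    dgamma = (dy * u_hat).sum(axis=0)
    dbeta = dy.sum(axis=0)
    dxhat = dy * state.gamma
    dx = (inv_std / n) * (n * dxhat - dxhat.sum(axis=0) - u_hat * (dxhat * u_hat).sum(axis=0))
    return dx, dgamma, dbeta


class BatchNorm(Layer):
    """Spatial batch norm over an NHWC tensor (one feature per channel)."""

    def __init__(self, n_features: int, eps: float = DEFAULT_BN_EPS,
                 momentum: float = DEFAULT_BN_MOMENTUM):
        self.state = BatchNormState.create(n_features, eps, momentum)
        self.dgamma = np.zeros(n_features, dtype=np.float32)
        self.dbeta = np.zeros(n_features, dtype=np.float32)

    def forward(self, x, mode="infer", rng=None):
        # Same math as batch_norm_forward, with fused statistics (single
        # einsum pass) and a fused affine, for throughput on large
        # spatial batches.
        self._shape = x.shape
        st = self.state
        flat = x.reshape(-1, x.shape[-1])
        n = flat.shape[0]
        if mode == "train":
            if n < 2:
                raise ValueError("batch normalization in train mode requires batch size >= 2")
            mean = np.einsum("nc->c", flat) / n
            var = np.einsum("nc,nc->c", flat, flat) / n - mean * mean
            var = np.maximum(var, 0.0)
            m = st.momentum
            st.running_mean[:] = m * st.running_mean + (1 - m) * mean
            st.running_var[:] = m * st.running_var + (1 - m) * var
            st.n_updates += 1
        else:
            mean, var = st.inference_stats()
        inv_std = (1.0 / np.sqrt(var + st.eps)).astype(flat.dtype)
        scale = st.gamma * inv_std
        shift = st.beta - mean * scale
        out = flat * scale + shift
        if mode == "train":
            self._cache = (flat, mean.astype(flat.dtype), inv_std)
        return out.reshape(self._shape)

    def backward(self, dy):
        flat_u, mean, inv_std = self._cache
        dyf = dy.reshape(-1, dy.shape[-1])
        n = dyf.shape[0]
        u_hat = (flat_u - mean) * inv_std
        dgamma = np.einsum("nc,nc->c", dyf, u_hat)
        dbeta = np.einsum("nc->c", dyf)
        self.dgamma[:], self.dbeta[:] = dgamma, dbeta
        scale = (self.state.gamma * inv_std).astype(dyf.dtype)
        dx = scale * (dyf - dbeta / n - u_hat * (dgamma / n))
        self._cache = None
        return dx.reshape(self._shape)

    @property
    def params(self):
        return {"gamma": self.state.gamma, "beta": self.state.beta}

    @property
    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x, mode="infer", rng=None):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        win = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        win = win.reshape(n, h // 2, w // 2, 4, c)
        arg = win.argmax(axis=3)
        y = np.take_along_axis(win, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if mode == "train":
            self._arg, self._in_shape = arg, x.shape
        return y

    def backward(self, dy):
        n, h, w, c = self._in_shape
        dwin = np.zeros((n, h // 2, w // 2, 4, c), dtype=dy.dtype)
        np.put_along_axis(dwin, self._arg[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = dwin.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return dx.reshape(n, h, w, c)


class Flatten(Layer):
    def forward(self, x, mode="infer", rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, mode="infer", rng=None):
        if mode == "train":
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[:] = self._x.T @ dy
        self.db[:] = dy.sum(axis=0)
        self._x = None
        return dy @ self.W.T

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def grads(self):
        return {"W": self.dW, "b": self.db}


class Dropout(Layer):
    """Inverted dropout: active only in train mode."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p

    def forward(self, x, mode="infer", rng=None):
        if mode != "train" or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("dropout in train mode needs an rng")
        # mask must match x's dtype: a float64 mask would promote the whole
        # backward chain off the fast single-precision BLAS path
        self._mask = ((rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        if self.p == 0.0:
            return dy
        return dy * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, y: np.ndarray):
    """Categorical cross-entropy between labels and softmax predictions.

    Returns (mean loss, gradient wrt logits)."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = -np.log(np.maximum(probs[np.arange(n), y], 1e-300)).mean()
    dlogits = probs
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(logits.dtype)
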