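"""A small 1-D convolutional network written directly on numpy.

Architecture (matching the classifier this package implements):

    [conv1d('same', stride 1) -> ReLU -> max-pool -> batch-norm] x n_stages
    -> dropout -> flatten -> Dense+ReLU chain -> Dense(n_classes) -> softmax

Convolutions run as im2col + BLAS matmul; gradients are hand-derived and
checked against finite differences in the test-suite. Pooling uses floor
division (a trailing remainder of the spatial axis is dropped), so the
flattened feature count is

    (image_length // pool ** n_stages) * final_filters

e.g. 1152 -> 144 spatial positions x 256 channels = 36,864.

Weights and activations are float32 by default (float64 is available for
finite-difference verification); everything is fully deterministic given
the seeds supplied by the caller - there is no hidden global RNG state.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvNet", "Adam", "softmax", "flatten_size"]


def softmax(logits: np.ndarray) -> np.ndarray:
    logits = np.asarray(logits, dtype=np.float64)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def flatten_size(image_length: int, n_stages: int, pool_width: int, final_filters: int) -> int:
    length = image_length
    for _ in range(n_stages):
        length //= pool_width
    return length * final_filters


class _Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class _Conv1d:
    """'same'-padded stride-1 1-D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator, dtype):
        fan_in = c_in * kernel
        self.kernel = kernel
        self.c_in = c_in
        self.W = _Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)).astype(dtype))
        self.b = _Param(np.zeros(c_out, dtype=dtype))

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:  # x: (N, C, L)
        k = self.kernel
        left = (k - 1) // 2
        n, c, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (left, k - 1 - left)))
        # (N, C, L, k) -> (N, L, C*k)
        cols = sliding_window_view(xp, k, axis=2).transpose(0, 2, 1, 3).reshape(n * length, c * k)
        self._cols = cols
        self._shape = (n, c, length)
        y = cols @ self.W.value + self.b.value
        return y.reshape(n, length, -1).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        k = self.kernel
        left = (k - 1) // 2
        dy2 = dy.transpose(0, 2, 1).reshape(n * length, -1)
        self.W.grad += self._cols.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        dcols = (dy2 @ self.W.value.T).reshape(n, length, c, k)
        dxp = np.zeros((n, c, length + k - 1), dtype=dy.dtype)
        for j in range(k):
            dxp[:, :, j : j + length] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, left : left + length]


class _ReLU:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _MaxPool1d:
    params: list = []

    def __init__(self, width: int):
        self.width = width

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        w = self.width
        l_out = length // w
        trimmed = x[:, :, : l_out * w].reshape(n, c, l_out, w)
        self._argmax = trimmed.argmax(axis=3)
        self._in_shape = x.shape
        return trimmed.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, l_out = dy.shape
        w = self.width
        dx = np.zeros((n, c, l_out, w), dtype=dy.dtype)
        np.put_along_axis(dx, self._argmax[..., None], dy[..., None], axis=3)
        out = np.zeros(self._in_shape, dtype=dy.dtype)
        out[:, :, : l_out * w] = dx.reshape(n, c, l_out * w)
        return out


class _BatchNorm1d:
    """Per-channel batch normalization over the (batch, spatial) axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = _Param(np.ones(channels, dtype=dtype))
        self.beta = _Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._xhat, self._inv_std = xhat, inv_std
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        m = dy.shape[0] * dy.shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        g = self.gamma.value[None, :, None] * inv_std[None, :, None]
        mean_dy = dy.sum(axis=(0, 2))[None, :, None] / m
        mean_dy_xhat = (dy * xhat).sum(axis=(0, 2))[None, :, None] / m
        return g * (dy - mean_dy - xhat * mean_dy_xhat)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = _Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(dtype))
        self.b = _Param(np.zeros(n_out, dtype=dtype))

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class ConvNet:
    """The full conv -> pool -> batch-norm stack with an FC head."""

    def __init__(
        self,
        image_length: int,
        conv_filters: list[int],
        kernel: int,
        pool_width: int,
        fc_sizes: list[int],
        n_classes: int,
        dropout_rate: float,
        seed: int,
        dtype=np.float32,
    ):
        rng = np.random.default_rng(seed)
        self.dtype = np.dtype(dtype)
        self.image_length = image_length
        self.pool_width = pool_width
        self.dropout_rate = dropout_rate
        self.n_classes = n_classes

        self.blocks = []
        c_in = 1
        length = image_length
        for c_out in conv_filters:
            self.blocks.append(
                {
                    "conv": _Conv1d(c_in, c_out, kernel, rng, self.dtype),
                    "relu": _ReLU(),
                    "pool": _MaxPool1d(pool_width),
                    "bn": _BatchNorm1d(c_out, dtype=self.dtype),
                }
            )
            c_in = c_out
            length //= pool_width
        if length < 1:
            raise ValueError(
                f"image_length {image_length} collapses to zero after "
                f"{len(conv_filters)} poolings of width {pool_width}"
            )
        self.feature_shape = (c_in, length)
        self.flat_size = c_in * length

        self.fcs: list[_Dense] = []
        self.fc_relus: list[_ReLU] = []
        n_in = self.flat_size
        for n_out in fc_sizes:
            self.fcs.append(_Dense(n_in, n_out, rng, self.dtype))
            self.fc_relus.append(_ReLU())
            n_in = n_out
        self.head = _Dense(n_in, n_classes, rng, self.dtype)

    # -- parameter plumbing ------------------------------------------------
    @property
    def params(self) -> list[_Param]:
        out = []
        for blk in self.blocks:
            out += blk["conv"].params + blk["bn"].params
        for fc in self.fcs:
            out += fc.params
        out += self.head.params
        return out

    def zero_grads(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params]
        for blk in self.blocks:
            state += [blk["bn"].running_mean.copy(), blk["bn"].running_var.copy()]
        return state

    def set_weights(self, state: list[np.ndarray]) -> None:
        params = self.params
        for p, v in zip(params, state[: len(params)]):
            p.value[...] = v
        rest = state[len(params) :]
        for i, blk in enumerate(self.blocks):
            blk["bn"].running_mean[...] = rest[2 * i]
            blk["bn"].running_var[...] = rest[2 * i + 1]

    # -- forward / backward ------------------------------------------------
    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """x: (N, image_length) scaled intensities -> logits (N, n_classes)."""
        h = np.asarray(x, dtype=self.dtype)[:, None, :]
        for blk in self.blocks:
            h = blk["conv"].forward(h)
            h = blk["relu"].forward(h)
            h = blk["pool"].forward(h)
            # CAM features: the rectified pooled maps (non-negative), pre batch-norm
            self._features_prebn = h
            h = blk["bn"].forward(h, train=train)
        self._features = h  # final block output (post batch-norm), the FC head's input
        flat = h.reshape(h.shape[0], -1)
        if train and self.dropout_rate > 0:
            if rng is None:
                raise ValueError("training-mode forward with dropout needs an rng")
            keep = 1.0 - self.dropout_rate
            self._drop_mask = ((rng.random(flat.shape) < keep) / keep).astype(self.dtype)
            flat = flat * self._drop_mask
        else:
            self._drop_mask = None
        for fc, relu in zip(self.fcs, self.fc_relus):
            flat = relu.forward(fc.forward(flat))
        return self.head.forward(flat)

    def backward_from_logits(self, dlogits: np.ndarray) -> np.ndarray:
        """Propagate d(objective)/d(logits) back; returns grad at the final block output."""
        d = self.head.backward(dlogits)
        for fc, relu in zip(reversed(self.fcs), reversed(self.fc_relus)):
            d = relu.backward(d)
            d = fc.backward(d)
        if self._drop_mask is not None:
            d = d * self._drop_mask
        return d.reshape(self._features.shape)

    def backward(self, dlogits: np.ndarray) -> None:
        """Full backward pass through the convolutional stack (for training)."""
        d = self.backward_from_logits(dlogits)
        for blk in reversed(self.blocks):
            d = blk["bn"].backward(d)
            d = blk["pool"].backward(d)
            d = blk["relu"].backward(d)
            d = blk["conv"].backward(d)

    def loss_and_grads(
        self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[float, float]:
        """Mean cross-entropy and accuracy on one minibatch; grads accumulated."""
        logits = self.forward(x, train=True, rng=rng)
        probs = softmax(logits)
        n = x.shape[0]
        loss = float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())
        acc = float((logits.argmax(axis=1) == y).mean())
        dlogits = probs.astype(self.dtype)
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        self.backward(dlogits)
        return loss, acc

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def features_and_logit_grad(self, x: np.ndarray, class_idx: int) -> tuple[np.ndarray, np.ndarray]:
        """Final-block rectified pooled activations and one class logit's gradient w.r.t. them.

        The activations are the max-pooled ReLU maps of the last
        convolutional stage, before batch normalization, so they are
        non-negative as CAM-style weighting assumes. Evaluation mode
        (running batch-norm statistics, no dropout); the gradient is of
        the raw logit, not the softmax probability.
        """
        logits = self.forward(x, train=False)
        dlogits = np.zeros(logits.shape, dtype=self.dtype)
        dlogits[:, class_idx] = 1.0
        dpost = self.backward_from_logits(dlogits)
        # in eval mode batch-norm is an affine map per channel
        bn = self.blocks[-1]["bn"]
        scale = bn.gamma.value / np.sqrt(bn.running_var + bn.eps)
        dfeat = dpost * scale[None, :, None]
        self.zero_grads()  # head/fc grads were a side effect; discard them
        return self._features_prebn.copy(), dfeat


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[_Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        # bias correction folded into the step size: identical update, fewer passes
        alpha = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        eps_hat = self.eps * np.sqrt(1 - b2**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad * p.grad - v)
            denom = np.sqrt(v)
            denom += eps_hat
            np.divide(m, denom, out=denom)
            denom *= alpha
            p.value -= denom
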