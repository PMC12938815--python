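"""Layer and optimizer classes on top of the autodiff tensors."""

from __future__ import annotations

import hashlib

import numpy as np

from .tensor import DTYPE, Tensor, avgpool_temporal, batch_norm, conv3d

__all__ = ["Conv3D", "BatchNorm", "AvgPool3D", "Activation", "Sequential", "Adam"]


class Layer:
    trainable = True

    def parameters(self) -> list[Tensor]:
        return []

    def forward(self, x: Tensor, training: bool) -> Tensor:
        raise NotImplementedError

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_digest(self) -> str:
        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()


class Conv3D(Layer):
    """'same'-padded stride-1 3-D convolution, channels-last, ReLU/sigmoid/linear."""

    def __init__(self, kernel: tuple[int, int, int], in_channels: int,
                 filters: int, *, use_bias: bool = True,
                 activation: str = "linear", rng: np.random.Generator | None = None):
        kt, kh, kw = kernel
        self.kernel = kernel
        self.filters = filters
        self.use_bias = use_bias
        self.activation = activation
        fan_in = kt * kh * kw * in_channels
        fan_out = kt * kh * kw * filters
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        rng = rng or np.random.default_rng()
        self.w = Tensor(rng.uniform(-limit, limit,
                                    (kt, kh, kw, in_channels, filters)).astype(DTYPE),
                        requires_grad=True)
        self.b = Tensor(np.zeros(filters, dtype=DTYPE), requires_grad=True) \
            if use_bias else None

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, training):
        out = conv3d(x, self.w, self.b, padding="same")
        if self.activation == "relu":
            return out.relu()
        if self.activation == "sigmoid":
            return out.sigmoid()
        return out


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)
        self.running = {"mean": np.zeros(channels, dtype=DTYPE),
                        "var": np.ones(channels, dtype=DTYPE)}
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        return batch_norm(x, self.gamma, self.beta, self.running,
                          training, self.momentum, self.eps)


class AvgPool3D(Layer):
    """Temporal-only average pooling (pool x 1 x 1), as in the decoder stacks."""

    trainable = False

    def __init__(self, pool_t: int):
        self.pool_t = pool_t

    def forward(self, x, training):
        return avgpool_temporal(x, self.pool_t)


class Activation(Layer):
    trainable = False

    def __init__(self, kind: str):
        self.kind = kind

    def forward(self, x, training):
        if self.kind == "relu":
            return x.relu()
        if self.kind == "sigmoid":
            return x.sigmoid()
        return x


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, training: bool = False) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    __call__ = forward

    def param_count(self) -> int:
        return sum(layer.param_count() for layer in self.layers)

    def state_digest(self) -> str:
        h = hashlib.sha256()
        for layer in self.layers:
            h.update(layer.state_digest().encode())
        return h.hexdigest()

    def set_trainable(self, flag: bool) -> None:
        for p in self.parameters():
            p.requires_grad = flag

    def get_state(self) -> list:
        """Deep copy of all parameters and batch-norm running statistics."""
        state = [p.data.copy() for p in self.parameters()]
        for layer in self.layers:
            running = getattr(layer, "running", None)
            if running is not None:
                state.append({k: v.copy() for k, v in running.items()})
        return state

    def set_state(self, state: list) -> None:
        params = self.parameters()
        for p, data in zip(params, state[:len(params)]):
            p.data = data.copy()
        extras = iter(state[len(params):])
        for layer in self.layers:
            if getattr(layer, "running", None) is not None:
                layer.running = {k: v.copy() for k, v in next(extras).items()}


class Adam:
    """Adaptive-moment estimation with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
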