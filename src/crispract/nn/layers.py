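"""Layers with forward/backward passes.

Each layer owns ``params`` and ``grads`` dicts keyed by parameter name.
``forward`` caches what ``backward`` needs; ``backward`` consumes the cache,
accumulates parameter gradients, and returns the gradient w.r.t. the input.
"""

from __future__ import annotations

import numpy as np


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class Layer:
    """Base layer: named, with (possibly empty) parameters."""

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def init(self, rng: np.random.Generator) -> None:  # pragma: no cover - overridden
        pass

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, name: str, in_features: int, units: int, activation: str = "linear"):
        super().__init__(name)
        if activation not in ("linear", "relu"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.in_features = in_features
        self.units = units
        self.activation = activation

    def init(self, rng: np.random.Generator) -> None:
        self.params = {
            "W": _glorot(rng, (self.in_features, self.units), self.in_features, self.units),
            "b": np.zeros(self.units),
        }
        self.zero_grads()

    def forward(self, x, train=False, rng=None):
        z = x @ self.params["W"] + self.params["b"]
        y = np.maximum(z, 0.0) if self.activation == "relu" else z
        self._cache = (x, z)
        return y

    def backward(self, dout):
        x, z = self._cache
        dz = dout * (z > 0) if self.activation == "relu" else dout
        self.grads["W"] += x.T @ dz
        self.grads["b"] += dz.sum(axis=0)
        return dz @ self.params["W"].T


class Conv1D(Layer):
    """Valid-padding 1-D convolution over (batch, length, channels)."""

    def __init__(self, name: str, in_channels: int, filters: int, kernel: int,
                 activation: str = "relu"):
        super().__init__(name)
        if activation not in ("linear", "relu"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.in_channels = in_channels
        self.filters = filters
        self.kernel = kernel
        self.activation = activation

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.kernel * self.in_channels
        self.params = {
            "W": _glorot(rng, (self.kernel, self.in_channels, self.filters), fan_in, self.filters),
            "b": np.zeros(self.filters),
        }
        self.zero_grads()

    def out_len(self, in_len: int) -> int:
        return in_len - self.kernel + 1

    def forward(self, x, train=False, rng=None):
        B, L, _ = x.shape
        Lo = self.out_len(L)
        if Lo < 1:
            raise ValueError(f"{self.name}: input length {L} < kernel {self.kernel}")
        z = np.broadcast_to(self.params["b"], (B, Lo, self.filters)).copy()
        W = self.params["W"]
        for i in range(self.kernel):
            z += x[:, i: i + Lo, :] @ W[i]
        y = np.maximum(z, 0.0) if self.activation == "relu" else z
        self._cache = (x, z, Lo)
        return y

    def backward(self, dout):
        x, z, Lo = self._cache
        dz = dout * (z > 0) if self.activation == "relu" else dout
        W = self.params["W"]
        dx = np.zeros_like(x)
        flat = dz.reshape(-1, self.filters)
        for i in range(self.kernel):
            xi = x[:, i: i + Lo, :].reshape(-1, self.in_channels)
            self.grads["W"][i] += xi.T @ flat
            dx[:, i: i + Lo, :] += dz @ W[i].T
        self.grads["b"] += flat.sum(axis=0)
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling over the length axis (remainder dropped)."""

    def __init__(self, name: str, pool: int = 2):
        super().__init__(name)
        self.pool = pool

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        Lo = L // self.pool
        xt = x[:, : Lo * self.pool, :].reshape(B, Lo, self.pool, C)
        arg = xt.argmax(axis=2)
        self._cache = (x.shape, arg)
        return np.take_along_axis(xt, arg[:, :, None, :], axis=2).squeeze(2)

    def backward(self, dout):
        shape, arg = self._cache
        B, L, C = shape
        Lo = L // self.pool
        dxt = np.zeros((B, Lo, self.pool, C), dtype=dout.dtype)
        np.put_along_axis(dxt, arg[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros(shape, dtype=dout.dtype)
        dx[:, : Lo * self.pool, :] = dxt.reshape(B, Lo * self.pool, C)
        return dx


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._cache = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._cache)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, name: str, rate: float):
        super().__init__(name)
        if not 0.0 <= rate < 1.0:
            raise ValueError("rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._cache = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        self._cache = mask
        return x * mask

    def backward(self, dout):
        return dout if self._cache is None else dout * self._cache


class _GRUDirection:
    """One GRU direction: parameters stored in the owning BiGRU layer under a
    prefix.  Update-gate convention: h_t = (1-z)*h_prev + z*h_tilde."""

    def __init__(self, owner: "BiGRU", prefix: str):
        self.owner = owner
        self.prefix = prefix

    def _p(self, key: str) -> np.ndarray:
        return self.owner.params[self.prefix + key]

    def _g(self, key: str) -> np.ndarray:
        return self.owner.grads[self.prefix + key]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        B, T, _ = x.shape
        U = self.owner.units
        Wz, Wr, Wh = self._p("Wz"), self._p("Wr"), self._p("Wh")
        Uz, Ur, Uh = self._p("Uz"), self._p("Ur"), self._p("Uh")
        bz, br, bh = self._p("bz"), self._p("br"), self._p("bh")
        h = np.zeros((B, U))
        cache = []
        for t in range(T):
            xt = x[:, t, :]
            z = _sigmoid(xt @ Wz + h @ Uz + bz)
            r = _sigmoid(xt @ Wr + h @ Ur + br)
            hh = np.tanh(xt @ Wh + (r * h) @ Uh + bh)
            h_new = (1.0 - z) * h + z * hh
            cache.append((xt, h, z, r, hh))
            h = h_new
        return h, cache

    def backward(self, dh: np.ndarray, cache: list, dx: np.ndarray) -> None:
        """Accumulate parameter grads and write input grads into ``dx``
        (same time order as the cache)."""
        Wz, Wr, Wh = self._p("Wz"), self._p("Wr"), self._p("Wh")
        Uz, Ur, Uh = self._p("Uz"), self._p("Ur"), self._p("Uh")
        for t in range(len(cache) - 1, -1, -1):
            xt, h_prev, z, r, hh = cache[t]
            dz = dh * (hh - h_prev)
            dhh = dh * z
            dh_prev = dh * (1.0 - z)
            da_h = dhh * (1.0 - hh * hh)
            self._g("Wh")[...] += xt.T @ da_h
            self._g("Uh")[...] += (r * h_prev).T @ da_h
            self._g("bh")[...] += da_h.sum(axis=0)
            drh = da_h @ Uh.T
            dr = drh * h_prev
            dh_prev += drh * r
            da_z = dz * z * (1.0 - z)
            da_r = dr * r * (1.0 - r)
            self._g("Wz")[...] += xt.T @ da_z
            self._g("Uz")[...] += h_prev.T @ da_z
            self._g("bz")[...] += da_z.sum(axis=0)
            self._g("Wr")[...] += xt.T @ da_r
            self._g("Ur")[...] += h_prev.T @ da_r
            self._g("br")[...] += da_r.sum(axis=0)
            dx[:, t, :] += da_z @ Wz.T + da_r @ Wr.T + da_h @ Wh.T
            dh = dh_prev + da_z @ Uz.T + da_r @ Ur.T


class BiGRU(Layer):
    """Bidirectional GRU returning the concatenated final hidden states of
    both directions: (batch, T, C) -> (batch, 2*units)."""

    def __init__(self, name: str, in_channels: int, units: int):
        super().__init__(name)
        self.in_channels = in_channels
        self.units = units
        self.fwd = _GRUDirection(self, "f_")
        self.bwd = _GRUDirection(self, "b_")

    def init(self, rng: np.random.Generator) -> None:
        C, U = self.in_channels, self.units
        self.params = {}
        for prefix in ("f_", "b_"):
            for gate in "zrh":
                self.params[f"{prefix}W{gate}"] = _glorot(rng, (C, U), C, U)
                self.params[f"{prefix}U{gate}"] = _glorot(rng, (U, U), U, U)
                self.params[f"{prefix}b{gate}"] = np.zeros(U)
        self.zero_grads()

    def forward(self, x, train=False, rng=None):
        hf, cf = self.fwd.forward(x)
        hb, cb = self.bwd.forward(x[:, ::-1, :])
        self._cache = (x.shape, cf, cb)
        return np.concatenate([hf, hb], axis=1)

    def backward(self, dout):
        shape, cf, cb = self._cache
        U = self.units
        dx = np.zeros(shape)
        self.fwd.backward(dout[:, :U], cf, dx)
        dx_rev = np.zeros(shape)
        self.bwd.backward(dout[:, U:], cb, dx_rev)
        dx += dx_rev[:, ::-1, :]
        return dx
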