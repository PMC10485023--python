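"""Adam optimizer over named layer parameters."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[tuple[str, str], np.ndarray] = {}
        self._v: dict[tuple[str, str], np.ndarray] = {}

    def step(self, layers: list[Layer], trainable: set[str]) -> None:
        """Apply one update to the parameters of layers in ``trainable``.

        Frozen layers are never touched, so their weights stay bit-identical.
        """
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for layer in layers:
            if layer.name not in trainable:
                continue
            for key, param in layer.params.items():
                grad = layer.grads[key]
                sk = (layer.name, key)
                m = self._m.setdefault(sk, np.zeros_like(param))
                v = self._v.setdefault(sk, np.zeros_like(param))
                m *= self.beta1
                m += (1.0 - self.beta1) * grad
                v *= self.beta2
                v += (1.0 - self.beta2) * grad * grad
                param -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
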