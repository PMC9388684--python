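"""Nadam: Adam with Nesterov momentum (Dozat 2016 formulation)."""

from __future__ import annotations

import numpy as np

__all__ = ["Nadam"]


class Nadam:
    def __init__(self, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self, params: dict[str, dict[str, np.ndarray]],
             grads: dict[str, dict[str, np.ndarray]], lr: float) -> None:
        """In-place Nadam update of every parameter that received a gradient."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc1_next = 1.0 - b1 ** (self.t + 1)
        bc2 = 1.0 - b2**self.t
        for name, g in grads.items():
            for key, grad in g.items():
                sk = f"{name}::{key}"
                m = self._m.get(sk)
                v = self._v.get(sk)
                if m is None:
                    m = np.zeros_like(grad, dtype=np.float64)
                    v = np.zeros_like(grad, dtype=np.float64)
                m = b1 * m + (1 - b1) * grad
                v = b2 * v + (1 - b2) * grad**2
                self._m[sk], self._v[sk] = m, v
                m_hat = b1 * m / bc1_next + (1 - b1) * grad / bc1
                v_hat = v / bc2
                params[name][key] -= (lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(
                    params[name][key].dtype)
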