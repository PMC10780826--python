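"""Adadelta optimizer (the classic parameterisation).

Adadelta keeps running averages of squared gradients and squared updates,

    E[g^2] <- rho E[g^2] + (1 - rho) g^2
    dx      = - RMS(dx) / RMS(g) * g
    E[dx^2] <- rho E[dx^2] + (1 - rho) dx^2
    x      <- x + lr * dx

with RMS(v) = sqrt(E[v^2] + eps). Defaults rho = 0.95, eps = 1e-6, lr = 1.0
follow the original algorithm, which was designed to run without a tuned
learning rate.
"""

from __future__ import annotations

import numpy as np


class Adadelta:
    def __init__(self, lr: float = 1.0, rho: float = 0.95, eps: float = 1e-6):
        self.lr, self.rho, self.eps = lr, rho, eps
        self._Eg: dict[str, np.ndarray] = {}
        self._Edx: dict[str, np.ndarray] = {}

    def step(self, model) -> None:
        """Apply one update using the gradients currently stored on layers."""
        for key, layer, name in model.param_items():
            g = layer.grads.get(name)
            if g is None:
                continue
            k = f"{key}:{name}"
            if k not in self._Eg:
                self._Eg[k] = np.zeros_like(g)
                self._Edx[k] = np.zeros_like(g)
            Eg, Edx = self._Eg[k], self._Edx[k]
            Eg *= self.rho
            Eg += (1.0 - self.rho) * g * g
            dx = -np.sqrt((Edx + self.eps) / (Eg + self.eps)) * g
            Edx *= self.rho
            Edx += (1.0 - self.rho) * dx * dx
            layer.params[name] += self.lr * dx
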