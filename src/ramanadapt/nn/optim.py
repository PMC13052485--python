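"""Adam optimizer over a named parameter dictionary."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Adam with bias-corrected moments, updating arrays in place.

    ``params`` and ``grads`` are name -> array mappings that stay live
    between steps (the model owns the arrays); ``trainable`` restricts
    updates to a subset of names, which is how layer freezing and test-time
    adaptation's parameter selection are enforced — frozen parameters are
    never touched, not merely given zero updates.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        trainable: set[str] | None = None,
    ) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.trainable = set(params) if trainable is None else set(trainable)
        unknown = self.trainable - set(params)
        if unknown:
            raise ValueError(f"unknown trainable parameter names: {sorted(unknown)}")
        self._m = {k: np.zeros_like(params[k]) for k in self.trainable}
        self._v = {k: np.zeros_like(params[k]) for k in self.trainable}
        self._t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self._t
        bc2 = 1.0 - b2**self._t
        for k in self.trainable:
            g = grads.get(k)
            if g is None:
                continue
            m = self._m[k]
            v = self._v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            self.params[k] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
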