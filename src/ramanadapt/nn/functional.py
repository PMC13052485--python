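"""Objective functions and their logit-space gradients."""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "softmax_cross_entropy", "entropy_grad_logits"]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer labels under softmax logits.

    Returns ``(loss, dloss/dlogits)``; for two classes this is the binary
    cross-entropy expressed over an explicit two-logit distribution.
    """
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def entropy_grad_logits(logits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shannon entropy of softmax(logits) per row and its logit gradient.

    With ``p = softmax(z)`` and ``H = -sum_c p_c log p_c`` the gradient is
    ``dH/dz_j = -p_j (log p_j + H)``.  Returns ``(H per row, dH/dz)`` where
    the gradient is of the summed entropy over rows.
    """
    p = softmax(logits)
    eps = 1e-12
    logp = np.log(p + eps)
    h = -(p * logp).sum(axis=-1)
    grad = -p * (logp + h[:, None])
    return h, grad
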