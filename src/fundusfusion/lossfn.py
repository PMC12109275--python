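"""Modulated binary cross-entropy loss and the decision rule.

The training objective is a focal-style weighted cross-entropy

    L = -y (1-p)^alpha * beta * ln(p)  -  (1-y) p^alpha * beta * ln(1-p)

where ``p`` is the sigmoid output of the network and ``y`` in {0, 1}
marks an early-glaucoma (1) vs healthy (0) eye.  The ``(1-p)^alpha``
factor down-weights well-classified samples (as in focal losses); the
exponent ``beta`` on the probability inside the log acts as a constant
gain ``beta * ln(p)``.  With alpha=0, beta=1 the loss reduces exactly to
binary cross-entropy.  Defaults alpha=1, beta=1.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Probability clamp to keep logarithms finite.
EPSILON = 1e-7


@dataclass(frozen=True)
class LossParams:
    """Exponents of the modulated cross-entropy loss."""

    alpha: float = 1.0
    beta: float = 1.5
    epsilon: float = EPSILON

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha}")
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise ValueError(f"beta must be finite and > 0, got {self.beta}")
        if not 0 < self.epsilon < 0.5:
            raise ValueError(f"epsilon must be in (0, 0.5), got {self.epsilon}")


def _validate_y(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be 0 or 1")
    return y


def concat_loss(
    y: np.ndarray | float,
    p_hat: np.ndarray | float,
    params: LossParams = LossParams(),
    reduction: str = "mean",
) -> float | np.ndarray:
    """Evaluate the modulated cross-entropy loss.

    Parameters
    ----------
    y : array-like of {0, 1}
    p_hat : array-like of probabilities
        Clamped to ``[epsilon, 1-epsilon]`` before the logarithm.
    reduction : {"mean", "none"}
        ``"mean"`` (default) averages over the batch.
    """
    y = _validate_y(np.atleast_1d(y))
    p = np.clip(np.asarray(p_hat, dtype=float), params.epsilon, 1.0 - params.epsilon)
    p = np.atleast_1d(p)
    loss = -y * (1.0 - p) ** params.alpha * params.beta * np.log(p) - (1.0 - y) * (
        p**params.alpha
    ) * params.beta * np.log(1.0 - p)
    if reduction == "mean":
        return float(np.mean(loss))
    if reduction == "none":
        return loss
    raise ValueError(f"unknown reduction {reduction!r}")


def concat_loss_grad(
    y: np.ndarray | float,
    p_hat: np.ndarray | float,
    params: LossParams = LossParams(),
) -> np.ndarray:
    """Analytic derivative dL/dp of the per-sample loss.

    For y=1:  d/dp [-(1-p)^a * b * ln p] = a (1-p)^(a-1) b ln p - (1-p)^a b / p
    For y=0:  d/dp [-(p)^a * b * ln(1-p)] = -a p^(a-1) b ln(1-p) + p^a b / (1-p)

    The gradient is zero where the clamp is active.
    """
    y = _validate_y(np.atleast_1d(y))
    p_raw = np.atleast_1d(np.asarray(p_hat, dtype=float))
    p = np.clip(p_raw, params.epsilon, 1.0 - params.epsilon)
    a, b = params.alpha, params.beta
    # a * (1-p)^(a-1) with the a=0 and p=1 corner handled: term vanishes when a=0
    pow_pos = a * (1.0 - p) ** (a - 1.0) if a != 0 else np.zeros_like(p)
    pow_neg = a * p ** (a - 1.0) if a != 0 else np.zeros_like(p)
    g_pos = pow_pos * b * np.log(p) - (1.0 - p) ** a * b / p
    g_neg = -pow_neg * b * np.log(1.0 - p) + p**a * b / (1.0 - p)
    grad = y * g_pos + (1.0 - y) * g_neg
    # clamped region: loss is flat in p_raw
    grad = np.where((p_raw < params.epsilon) | (p_raw > 1.0 - params.epsilon), 0.0, grad)
    return grad


def predict_label(p_hat: np.ndarray | float) -> np.ndarray | int:
    """Map probability to a binary label: 1 iff ``p_hat > 0.5`` (strict)."""
    p = np.asarray(p_hat, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p_hat must lie in [0, 1]")
    labels = (p > 0.5).astype(int)
    if np.isscalar(p_hat) or np.ndim(p_hat) == 0:
        return int(labels)
    return labels
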