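"""Gradient-based feature importance.

The importance of feature j is the mean absolute partial derivative of the
per-sample cross-entropy loss with respect to input coordinate j,

    S_j = (1 / n_val) * sum_i | dL(y_i, O_i) / dx_ij |,

averaged over the validation samples.  A large S_j means perturbing gene j
moves the loss a lot, i.e. the fitted network relies on it.  Scores are
computed in evaluation mode (dropout off, batch-norm frozen) so that the
elimination decisions they drive are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import DenseClassifier

__all__ = ["ScoreVector", "importance_scores"]


@dataclass
class ScoreVector:
    """Per-feature importance scores over the currently active features."""

    scores: np.ndarray
    computed_on: str = "validation"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 1:
            raise ValueError("scores must be 1-D")
        if not np.all(np.isfinite(self.scores)) or np.any(self.scores < 0):
            raise ValueError("scores must be finite and non-negative")


def importance_scores(
    model: DenseClassifier,
    X_val: np.ndarray,
    y_val: np.ndarray,
    computed_on: str = "validation",
) -> ScoreVector:
    """Mean absolute input-gradient of the loss over the given samples."""
    X_val = np.asarray(X_val)
    if X_val.shape[0] == 0:
        raise ValueError("need at least one sample to score features")
    if X_val.shape[1] != model.n_features:
        raise ValueError(
            f"matrix has {X_val.shape[1]} columns but the model has {model.n_features} active features"
        )
    grads = model.input_gradients(X_val, np.asarray(y_val))
    return ScoreVector(np.mean(np.abs(grads.astype(np.float64)), axis=0), computed_on)
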