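"""Surrogate (known-null) feature construction.

q artificial features with no association to the class label are appended to
the expression matrix.  Their survival rate through backward elimination
calibrates the false-discovery-rate estimate for the real genes.  By default
q = floor(p / 2).

Two sampling strategies are provided:

``pooled`` (default)
    all n*p entries of the processed matrix are pooled and n*q of them are
    drawn without replacement, then arranged into q columns.  Each surrogate
    column follows the pooled marginal distribution of the data.
``column_permute``
    each surrogate is an independently row-permuted copy of a randomly chosen
    original column, preserving per-gene marginal distributions (closer to
    permutation-null practice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeaturePanel", "default_q", "make_surrogates", "attach_surrogates"]


@dataclass
class FeaturePanel:
    """Original features and surrogates side by side, with a surrogate mask."""

    matrix: np.ndarray  # (n, p + q)
    is_surrogate: np.ndarray  # (p + q,) bool

    @property
    def q(self) -> int:
        return int(self.is_surrogate.sum())

    @property
    def p(self) -> int:
        return int((~self.is_surrogate).sum())


def default_q(p: int) -> int:
    """Default surrogate count, floor(p / 2)."""
    return p // 2


def make_surrogates(
    X: np.ndarray,
    q: int,
    rng: np.random.Generator,
    strategy: str = "pooled",
) -> np.ndarray:
    """Build an (n, q) block of null features from ``X``."""
    X = np.asarray(X)
    n, p = X.shape
    if q < 0:
        raise ValueError("q must be >= 0")
    if q == 0:
        return np.empty((n, 0), dtype=X.dtype)
    if q > p:
        raise ValueError(f"cannot sample {n * q} entries without replacement from {n * p} (q > p)")
    if strategy == "pooled":
        flat_idx = rng.choice(n * p, size=n * q, replace=False)
        return X.ravel()[flat_idx].reshape(n, q).astype(X.dtype, copy=False)
    if strategy == "column_permute":
        cols = rng.integers(0, p, size=q)
        out = np.empty((n, q), dtype=X.dtype)
        for k, j in enumerate(cols):
            out[:, k] = X[rng.permutation(n), j]
        return out
    raise ValueError(f"unknown surrogate strategy {strategy!r}")


def attach_surrogates(X: np.ndarray, S: np.ndarray) -> FeaturePanel:
    """Concatenate originals and surrogates into one feature panel."""
    X = np.asarray(X)
    S = np.asarray(S)
    if X.shape[0] != S.shape[0]:
        raise ValueError("row counts of X and S differ")
    mask = np.concatenate([np.zeros(X.shape[1], bool), np.ones(S.shape[1], bool)])
    return FeaturePanel(np.hstack([X, S.astype(X.dtype, copy=False)]), mask)
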