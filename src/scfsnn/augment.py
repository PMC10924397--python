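"""Convex pseudodata (CPD) augmentation.

New training samples are convex combinations of two existing samples,

    x* = (1 - alpha) x_i + alpha x_j,   alpha ~ Uniform(0, d),

labelled with the first parent's class.  Because alpha < d < 1, the new point
stays close to its first parent, so the label is (approximately) preserved
while the training distribution is smoothed.  The single knob d defaults to
0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Labels

__all__ = ["CpdConfig", "cpd_augment"]


@dataclass
class CpdConfig:
    """Configuration of convex-pseudodata augmentation.

    ``n_new = None`` generates as many synthetic samples as there are
    originals (doubling the training set).  ``same_class_only`` restricts
    parent pairs to one class.
    """

    enabled: bool = True
    d: float = 0.2
    n_new: int | None = None
    same_class_only: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.d < 1.0:
            raise ValueError("mixing bound d must lie in (0, 1)")
        if self.n_new is not None and self.n_new < 0:
            raise ValueError("n_new must be >= 0")


def cpd_augment(
    X: np.ndarray,
    y: Labels,
    cfg: CpdConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, Labels]:
    """Append ``cfg.n_new`` convex-pseudodata rows to ``X``.

    Returns the originals unchanged followed by the synthetic rows; labels are
    extended with each synthetic row's first-parent label.
    """
    X = np.asarray(X)
    n = X.shape[0]
    if n == 0:
        raise ValueError("cannot augment an empty matrix")
    n_new = n if cfg.n_new is None else cfg.n_new
    if not cfg.enabled or n_new == 0:
        return X, y
    if n < 2:
        raise ValueError("need at least 2 samples to draw a parent pair")

    first = rng.integers(0, n, size=n_new)
    if cfg.same_class_only:
        second = np.empty(n_new, dtype=np.int64)
        for k, i in enumerate(first):
            pool = np.flatnonzero(y.y == y.y[i])
            pool = pool[pool != i]
            if pool.size == 0:
                raise ValueError(f"class {y.y[i]} has a single member; cannot pair within class")
            second[k] = rng.choice(pool)
    else:
        # uniform over j != i via a shifted draw
        second = rng.integers(0, n - 1, size=n_new)
        second[second >= first] += 1
    alpha = rng.uniform(0.0, cfg.d, size=n_new).astype(X.dtype, copy=False)

    new = (1.0 - alpha)[:, None] * X[first] + alpha[:, None] * X[second]
    X_out = np.vstack([X, new.astype(X.dtype, copy=False)])
    y_out = Labels(np.concatenate([y.y, y.y[first]]), y.n_classes)
    return X_out, y_out
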