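"""False-discovery-rate estimation for backward elimination.

With r features still active, of which r0 are surrogates out of q injected,
and p0_hat estimated nulls among the p original genes, the FDR of the r - r0
surviving originals is estimated as

    eta_hat = (r0 / q) * p0_hat / (r - r0).

p0 is estimated once, after the initialisation phase, from the importance
scores:  p0_hat = min(2 * #{original S_j < S_m}, p)  where S_m is the median
surrogate score — originals scoring below the surrogate median are likely
null, and under exchangeability they are about half of all nulls.

Each elimination step removes ceil(eps * (1 - eta_star / eta_hat) * r0)
features: aggressive while the estimated FDR is far above the target
eta_star, tapering to single deletions as it approaches it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FdrState",
    "estimate_p0",
    "estimate_fdr",
    "elimination_count",
    "should_stop",
]


@dataclass
class FdrState:
    """Snapshot of one elimination step."""

    r: int  # active features, originals + surrogates
    r0: int  # active surrogates
    q: int  # injected surrogates
    p0_hat: int  # estimated null originals
    eta_hat: float = math.nan
    eta_star: float = 0.1
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.r0 <= min(self.r, self.q):
            raise ValueError(f"need 0 <= r0 <= min(r, q); got r={self.r}, r0={self.r0}, q={self.q}")
        if not 0.0 < self.epsilon <= 1.0:
            raise ValueError("epsilon must be in (0, 1]")


def estimate_p0(
    scores_original: np.ndarray,
    scores_surrogate: np.ndarray,
    p: int,
) -> int:
    """Estimate the number of null genes among the p originals.

    Strict inequality: original scores exactly equal to the surrogate median
    do not count as below it.
    """
    scores_surrogate = np.asarray(scores_surrogate, dtype=np.float64)
    if scores_surrogate.size == 0:
        raise ValueError("surrogate score vector is empty")
    s_m = float(np.median(scores_surrogate))
    n_below = int(np.sum(np.asarray(scores_original, dtype=np.float64) < s_m))
    return min(2 * n_below, p)


def estimate_fdr(state: FdrState) -> float:
    """(r0/q) * p0_hat / (r - r0); +inf (with a warning) if only surrogates remain."""
    if state.r0 == 0:
        return 0.0
    if state.r == state.r0:
        warnings.warn("every retained feature is a surrogate; estimated FDR is infinite", stacklevel=2)
        return math.inf
    return (state.r0 / state.q) * state.p0_hat / (state.r - state.r0)


def elimination_count(eta_hat: float, eta_star: float, epsilon: float, r0: int) -> int:
    """Number of lowest-scoring features to delete this step.

    Assumes the loop has not stopped (eta_hat > eta_star); always >= 1 when
    r0 >= 1.  eta_hat = +inf (surrogates only) gives the maximal batch
    ceil(epsilon * r0).
    """
    frac = 0.0 if math.isinf(eta_hat) else eta_star / eta_hat
    return math.ceil(epsilon * (1.0 - frac) * r0)


def should_stop(eta_hat: float, eta_star: float) -> bool:
    """Selection stops once the estimated FDR has fallen to the target."""
    return eta_hat <= eta_star
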