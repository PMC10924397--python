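"""Deterministic fan-out of one user seed into per-component RNG streams.

Every stochastic component (data split, surrogate sampling, convex-pseudodata
augmentation, network initialisation/training, simulation) draws from its own
child stream so components can be re-run in isolation without perturbing the
others.
"""

from __future__ import annotations

import numpy as np

# stable component labels -> spawn keys
_COMPONENTS = ("split", "surrogate", "cpd", "net_init", "net_train", "sim", "final_model")


def component_rng(seed: int, component: str, extra: int = 0) -> np.random.Generator:
    """Return the RNG stream for one named component under a global seed.

    ``extra`` distinguishes repeated uses within a component (e.g. replicate
    index in a benchmark).
    """
    if component not in _COMPONENTS:
        raise ValueError(f"unknown RNG component {component!r}; expected one of {_COMPONENTS}")
    key = _COMPONENTS.index(component)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key, int(extra)))
    return np.random.default_rng(ss)
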