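"""Deterministic seeding with named substreams.

A single root seed is fanned out into independent substreams, one per named
operation, so that adding or reordering stochastic stages never perturbs the
draws of the others.
"""

from __future__ import annotations

import numpy as np

# Fixed substream ids; append-only so existing streams never move.
_STREAMS = {
    "ld_model": 1,
    "causal_labels": 2,
    "effect_sizes": 3,
    "target_noise": 4,
    "aux_noise": 5,
    "annotation": 6,
    "prune": 7,
    "bootstrap": 8,
    "third_trait": 9,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    try:
        key = _STREAMS[name]
    except KeyError:
        raise KeyError(f"unknown substream {name!r}; known: {sorted(_STREAMS)}")
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
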