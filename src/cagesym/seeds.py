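"""Root-seed management.

Every stochastic stage of the pipeline consumes its own named substream
derived from a single root seed, so that stages are independently
reproducible: changing the number of permutation iterations, say, does not
perturb the simulated read counts.
"""

from __future__ import annotations

import numpy as np

# Fixed substream indices; appending new names is safe, reordering is not.
_SUBSTREAMS = {
    "phylogeny": 0,
    "experiment": 1,
    "reads": 2,
    "climate": 3,
    "subsample": 4,
    "rarefy": 5,
    "permtest": 6,
    "pipeline": 7,
}


def substream_seed(root_seed: int, name: str) -> np.random.SeedSequence:
    """Derive the named substream's seed sequence from the root seed."""
    if name not in _SUBSTREAMS:
        raise KeyError(f"unknown substream {name!r}; known: {sorted(_SUBSTREAMS)}")
    return np.random.SeedSequence(root_seed, spawn_key=(_SUBSTREAMS[name],))


def substream(root_seed: int, name: str) -> np.random.Generator:
    """A fresh PCG64 generator for the named substream of ``root_seed``."""
    return np.random.default_rng(substream_seed(root_seed, name))


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce an int seed, Generator, or None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
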