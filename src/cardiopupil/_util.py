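"""Small shared helpers."""

from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.SeedSequence | np.random.Generator"


def as_rng(seed) -> np.random.Generator:
    """Return a Generator from an int, SeedSequence, or Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sem(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))
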