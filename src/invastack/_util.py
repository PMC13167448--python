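"""Shared helpers: seed derivation and smooth random fields."""

from __future__ import annotations

import zlib

import numpy as np
from scipy import ndimage

MAX_SEED = 2**31 - 1


def derive_seed(master: int, *tokens) -> int:
    """Derive a stage/species-specific seed from a master seed.

    Stable across platforms and processes (crc32 of the token repr folded
    into a SeedSequence), so every stochastic stage of a run is a pure
    function of the master seed and its own name.
    """
    h = zlib.crc32(repr(tokens).encode("utf-8"))
    ss = np.random.SeedSequence([int(master) % MAX_SEED, h])
    return int(ss.generate_state(1)[0] % MAX_SEED)


def smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise, standardized to zero mean / unit sd."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    sd = field.std()
    if sd == 0:  # pathological tiny grids
        return np.zeros(shape)
    return (field - field.mean()) / sd
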