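"""Deterministic seed derivation for replicate simulations.

Every replicate in a sweep gets its own seed that is a pure function of
(master seed, axis value, mode label, replicate index), so sweeps are
bit-reproducible and individual points can be re-run in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(master_seed: int, *keys) -> int:
    """Derive a sub-seed from a master seed and a tuple of hashable keys.

    The keys are rendered to a canonical string and hashed with CRC-32,
    then combined with the master seed through a SeedSequence.  The result
    is a non-negative integer below 2**31.
    """
    tag = "|".join(repr(k) for k in keys)
    crc = zlib.crc32(tag.encode("utf-8")) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, crc])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def derive_rng(master_seed: int, *keys) -> np.random.Generator:
    """A fresh Generator seeded via :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master_seed, *keys))
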