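"""Hierarchical seeding helpers.

All randomness in the package flows from one integer seed. Sub-streams are
derived with :class:`numpy.random.SeedSequence` using stable 32-bit keys
hashed from string/int labels, so adding a lesion or a stage never perturbs
the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key(part: object) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part) & 0xFFFFFFFF
    return zlib.crc32(str(part).encode("utf-8")) & 0xFFFFFFFF


def substream(seed: int, *parts: object) -> np.random.Generator:
    """Return a Generator for the sub-stream identified by ``parts``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_key(p) for p in parts))
    return np.random.default_rng(ss)


def subseed(seed: int, *parts: object) -> int:
    """Derive a plain integer seed (< 2**31) for libraries that need one."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_key(p) for p in parts))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
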