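"""Deterministic, component-keyed random streams.

Every stochastic step in the package draws from a Philox counter-based
generator seeded by ``(master_seed, component_key...)``.  Keys are hashed
with CRC32 into a :class:`numpy.random.SeedSequence` spawn key, so adding a
new consumer (e.g. more simulated traits) never perturbs the stream of an
existing one, and a fixed master seed gives bit-identical output across
platforms.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng"]


def _key_to_int(k: object) -> int:
    if isinstance(k, (int, np.integer)):
        return int(k) & 0xFFFFFFFF
    return zlib.crc32(str(k).encode("utf-8"))


def child_rng(master_seed: int, *key: object) -> np.random.Generator:
    """Return a Philox generator for the stream named by ``key``.

    Parameters
    ----------
    master_seed
        The run-level seed.
    *key
        Component name and indices, e.g. ``("genotypes", arm_index)``.
    """
    spawn = tuple(_key_to_int(k) for k in key)
    ss = np.random.SeedSequence(int(master_seed), spawn_key=spawn)
    return np.random.Generator(np.random.Philox(ss))
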