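"""Named, reproducible random substreams.

Every randomized stage of the pipeline draws from a substream identified
by a (master seed, named path) pair, so cohorts, subjects, permutations
and bootstrap draws are reproducible and independent of execution order.
Substreams are derived with ``numpy.random.SeedSequence`` spawn keys;
string keys are hashed stably with CRC-32.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0x7FFFFFFF
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    raise TypeError(f"substream keys must be int or str, got {type(key)!r}")


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys`` under ``seed``.

    The same (seed, keys) pair always yields the same stream; distinct
    key paths yield statistically independent streams.
    """
    spawn_key = tuple(_key_to_int(k) for k in keys)
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=spawn_key)
    return np.random.default_rng(ss)
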