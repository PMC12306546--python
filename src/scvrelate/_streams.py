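"""Named, order-independent random substreams.

A master seed plus a tuple of names/indices maps deterministically onto a
``numpy.random.Generator``.  Stages of the pipeline (simulation, each IVA
restart, each per-SCV bootstrap) draw from their own substream, so results do
not depend on execution order or parallelisation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError("substream integer keys must be non-negative")
        return int(key)
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    raise TypeError(f"substream keys must be int or str, got {type(key)!r}")


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys`` under ``seed``.

    The same (seed, keys) pair always yields a bit-identical stream;
    distinct key tuples yield statistically independent streams.
    """
    entropy = (int(seed),) + tuple(_key_to_int(k) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def as_rng(seed_or_rng: int | np.random.Generator, *keys: object) -> np.random.Generator:
    """Coerce an int seed (via :func:`substream`) or pass a Generator through."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return substream(int(seed_or_rng), *keys)
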