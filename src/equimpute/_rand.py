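"""Named substreams of a single master seed.

Every stochastic operation in the package draws from a stream derived from
``(seed, name)`` so that adding or reordering one stage never perturbs the
draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator keyed by a master seed and a path of stream names.

    The name path is hashed with CRC32 into the SeedSequence spawn key, so the
    mapping is stable across sessions and platforms.
    """
    key = tuple(zlib.crc32(str(n).encode("utf-8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))
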