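"""Named RNG substreams so every stage draws from an independent, reproducible stream."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream `name` of master `seed`.

    The substream key is a CRC32 of the name, so the stream depends only on
    (seed, name) and not on the order in which substreams are created.
    """
    key = zlib.crc32(name.encode("utf-8")) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))
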