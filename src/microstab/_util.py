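"""Shared helpers: deterministic seed substreams keyed by labels."""

from __future__ import annotations

import zlib

import numpy as np


def substream_rng(seed: int, *tokens) -> np.random.Generator:
    """Return a Generator on a substream keyed by (seed, *tokens).

    Tokens are hashed with CRC32 so substreams are keyed by label (e.g. a
    sample id), not by position, making results invariant to input ordering.
    """
    key = tuple(zlib.crc32(str(t).encode("utf-8")) for t in tokens)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))
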