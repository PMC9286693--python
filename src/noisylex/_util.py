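"""Deterministic seed derivation shared across modules.

Every stochastic stage derives its own seed from the master seed plus a
stable sequence of tags (strings are hashed with crc32), so a single master
seed reproduces the whole pipeline and no two stages share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master: int, *tags: int | str) -> int:
    """A 31-bit seed deterministically derived from a master seed and tags."""
    ints = [int(master) & 0x7FFFFFFF]
    for tag in tags:
        if isinstance(tag, str):
            ints.append(zlib.crc32(tag.encode()) & 0x7FFFFFFF)
        else:
            ints.append(int(tag) & 0x7FFFFFFF)
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
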