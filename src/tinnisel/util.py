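"""Small shared utilities."""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master: int, *tags: object) -> int:
    """Derive a child seed (< 2**31) from a master seed and string tags.

    The scheme is stable across runs and versions: each tag is hashed
    with CRC-32 and the whole tuple feeds a ``numpy`` ``SeedSequence``.
    Every source of randomness in the package draws its seed this way
    from one master seed.
    """
    entropy = [int(master) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(t).encode("utf-8")) for t in tags]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))
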