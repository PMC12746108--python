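"""Small shared helpers."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["spawn_seeds"]


def spawn_seeds(master_seed: int, n: int, tag: str = "") -> np.ndarray:
    """Derive ``n`` reproducible child seeds (< 2**31) from a master seed.

    Different ``tag`` strings give statistically independent streams, so
    e.g. shuffle seeds and fit seeds never collide.
    """
    tag_int = int.from_bytes(hashlib.blake2s(tag.encode(), digest_size=4).digest(), "big")
    ss = np.random.SeedSequence([int(master_seed), tag_int])
    return (ss.generate_state(n, np.uint64) % (2**31)).astype(np.int64)
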