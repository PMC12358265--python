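"""Deterministic random-stream management.

Every source of randomness in the package derives from a single root seed
through named substreams.  A substream is identified by the root seed plus a
sequence of string/int keys (stage name, patient index, fold number, ...);
string keys are hashed with BLAKE2s to a 32-bit word so the mapping is stable
across platforms and sessions.  Two substreams with different key paths are
statistically independent (numpy ``SeedSequence`` guarantees).
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def _key_word(key: str | int) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError("substream keys must be non-negative integers")
        return int(key)
    digest = hashlib.blake2s(str(key).encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def substream(seed: int, *keys: str | int) -> np.random.Generator:
    """Return the generator for the named substream of ``seed``."""
    entropy = [int(seed)] + [_key_word(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def spawn_seed(seed: int, *keys: str | int) -> int:
    """Derive a child integer seed (< 2**31) for the named substream."""
    entropy = [int(seed)] + [_key_word(k) for k in keys]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))
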