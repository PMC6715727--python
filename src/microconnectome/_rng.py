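"""Keyed random-number streams.

Every stochastic stage of the pipeline draws from its own stream, derived
from one root seed plus a string key naming the stage.  Re-running a single
stage in isolation therefore reproduces exactly the numbers it saw inside a
full pipeline run.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["keyed_rng", "keyed_seed"]


def _key_to_int(key: str) -> int:
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def keyed_rng(seed: int, *key: object) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a tuple of key parts."""
    parts = [int(seed) & 0xFFFFFFFF] + [_key_to_int(str(k)) for k in key]
    return np.random.default_rng(np.random.SeedSequence(parts))


def keyed_seed(seed: int, *key: object) -> int:
    """A derived integer seed below 2**31, for APIs that want a plain int."""
    parts = [int(seed) & 0xFFFFFFFF] + [_key_to_int(str(k)) for k in key]
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))
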