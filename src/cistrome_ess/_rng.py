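"""Per-operation random streams.

Every simulation operation draws from its own generator derived from the
master seed plus a stable hash of the operation name, so a stage can be
re-run in isolation and still reproduce the exact numbers of a full run.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the RNG stream for operation ``name`` under ``seed``."""
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    return np.random.default_rng([int(seed), zlib.crc32(name.encode("utf8"))])
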