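"""Reproducible named random substreams.

Every run (sweep cell x replicate, or time-series tick) gets its own
generator derived by hashing a label tuple together with the master seed, so
any single run can be reproduced in isolation and the presence of other runs
never perturbs it.
"""

from __future__ import annotations

import hashlib
from typing import Tuple

import numpy as np

__all__ = ["stream_seed", "derive_rng", "stream_label"]


def _canonical(part) -> bytes:
    if isinstance(part, bool):
        return b"b:" + (b"1" if part else b"0")
    if isinstance(part, (int, np.integer)):
        return b"i:" + str(int(part)).encode()
    if isinstance(part, (float, np.floating)):
        return b"f:" + repr(float(part)).encode()
    if isinstance(part, str):
        return b"s:" + part.encode()
    raise TypeError(f"unsupported stream-key part: {part!r}")


def stream_label(*key) -> str:
    """Human-readable form of a substream key, for manifests and logs."""
    return "/".join(str(k) for k in key)


def stream_seed(master_seed: int, *key) -> int:
    """Derive a 64-bit seed for the substream named by ``key``."""
    h = hashlib.blake2b(digest_size=8)
    h.update(_canonical(int(master_seed)))
    for part in key:
        h.update(b"\x1f")
        h.update(_canonical(part))
    return int.from_bytes(h.digest(), "little")


def derive_rng(master_seed: int, *key) -> np.random.Generator:
    """Generator for the substream named by ``key``."""
    return np.random.default_rng(stream_seed(master_seed, *key))
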