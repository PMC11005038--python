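"""Seed derivation shared across modules.

All stochastic components draw their seeds from one global seed through
a stable hash of string parts, so a pipeline run is reproducible from a
single integer.
"""

from __future__ import annotations

import hashlib


def derive_seed(global_seed: int, *parts) -> int:
    """Stable child seed from a global seed and context labels (< 2^31)."""
    key = ":".join([str(int(global_seed))] + [str(p) for p in parts])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)
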