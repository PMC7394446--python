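"""Small shared helpers."""

from __future__ import annotations

import hashlib


def stable_seed(seed: int, name: str) -> int:
    """Deterministic per-item seed derived from a global seed and an id.

    Hash-based so results are independent of iteration order and worker
    count; always < 2**31.
    """
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)
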