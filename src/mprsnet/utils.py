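"""Small shared helpers."""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(seed: int, label: str) -> int:
    """Derive a stable stage seed (< 2^31) from a global seed and a label."""
    digest = hashlib.blake2s(f"{seed}:{label}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)
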