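"""Seed plumbing shared across stages."""

from __future__ import annotations

import hashlib


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) derived from a global run seed."""
    digest = hashlib.blake2s(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
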