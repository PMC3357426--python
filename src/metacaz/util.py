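"""Small shared helpers."""

from __future__ import annotations

import zlib

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def derive_seed(seed: int, name: str) -> int:
    """Deterministically derive a per-stage child seed (< 2**31)."""
    return (int(seed) * 1000003 + zlib.crc32(name.encode())) % (2**31 - 1)
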