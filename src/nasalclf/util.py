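"""Seed fan-out and small shared helpers."""

from __future__ import annotations

import hashlib


def child_seed(master_seed: int, *parts) -> int:
    """Derive a reproducible child seed from a master seed and a stage path.

    The derivation is sha256 over the decimal master seed plus the stringified
    path components (e.g. ``("split", 7, "ranker", "LR-RFE")``), reduced mod
    2**31 so it is usable everywhere a 32-bit seed is expected.  Independent
    paths give effectively independent streams while staying reproducible.
    """
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for p in parts:
        h.update(b"/")
        h.update(str(p).encode())
    return int.from_bytes(h.digest()[:8], "big") % (2**31)
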