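"""Deterministic derivation of per-stage random seeds from one master seed."""

from __future__ import annotations

import hashlib


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a reproducible 31-bit seed for a named pipeline stage.

    A stable cryptographic hash of ``(master_seed, stage)`` keeps stage
    streams independent of each other and of Python's per-process hash
    randomization.
    """
    digest = hashlib.sha256(f"{int(master_seed)}::{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)
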