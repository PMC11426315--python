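"""Deterministic seed fan-out.

Every random draw in a pipeline run derives from one master seed via
``derive_seed(master, *tokens)`` — a SHA-256 hash of the master seed and
stage/item tokens, reduced below 2**31 — so stages can run in any order
or in parallel and still reproduce bit-identically.
"""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, *tokens) -> int:
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for t in tokens:
        h.update(b"|")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
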