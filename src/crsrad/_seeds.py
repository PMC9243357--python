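"""Reproducible seed derivation.

Every random draw in the package traces back to a base seed through
``derive_seed(base, stage, *indices)`` so stages, repetitions and folds are
statistically independent yet bit-reproducible.
"""

from __future__ import annotations

import hashlib


def derive_seed(base_seed: int, *parts: object) -> int:
    """Hash (base_seed, *parts) into a 31-bit RNG seed."""
    key = ":".join([str(int(base_seed))] + [str(p) for p in parts])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
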