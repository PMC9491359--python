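"""Small shared helpers: deterministic sub-seed derivation."""

from __future__ import annotations

import hashlib


def derive_seed(base_seed: int, *parts) -> int:
    """Derive a 31-bit sub-seed from a global seed and a label path.

    Hash-based so that e.g. adding subjects to a cohort leaves every existing
    (subject, condition, trial) stream unchanged.
    """
    key = "/".join([str(base_seed), *map(str, parts)])
    digest = hashlib.blake2b(key.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF
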