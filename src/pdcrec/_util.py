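"""Small shared helpers."""

from __future__ import annotations

import hashlib


def derive_seed(*parts: object) -> int:
    """Stable sub-seed from arbitrary labelled parts, below 2**31.

    Hash-based so that results do not depend on the order in which columns
    or cells happen to be processed.
    """
    text = "\x1f".join(repr(p) for p in parts)
    digest = hashlib.blake2b(text.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)
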