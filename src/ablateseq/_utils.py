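"""Small shared helpers."""
from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round ``x`` to ``decimals`` places with ties going away from zero.

    Printed percentages in result tables use this convention rather than
    banker's rounding, so 54.85 renders as 54.9.
    """
    if x != x:  # NaN
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
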