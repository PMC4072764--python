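"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, as printed tables do.

    Python's built-in ``round`` uses banker's rounding, which disagrees
    with the half-up convention of most published percentage tables
    (e.g. 28.57 % prints as 29 %, 0.25 prints as 0.3 at one decimal).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def derive_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from a top-level seed.

    Stable across runs and platforms (no reliance on hash randomisation).
    """
    h = 2166136261
    for ch in f"{seed}:{stage}".encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h % (2**31 - 1)
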