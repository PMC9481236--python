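"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

CHROM_ORDER = {f"chr{c}": i for i, c in enumerate(list(range(1, 23)) + ["X", "Y"])}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed clinical percentages are.

    Python's builtin round() is banker's rounding; yield percentages and
    per-trio costs in this package follow the half-up convention instead
    (139/264 -> 52.7, 172305/241 -> 715).
    """
    q = Decimal(1).scaleb(-ndigits)
    v = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(v) if ndigits > 0 else float(int(v))


def variant_key(family: str, chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{family}:{chrom}:{int(pos)}:{ref}:{alt}"


def chrom_sort_key(chrom: str) -> int:
    return CHROM_ORDER.get(chrom, 99)


def is_x(chrom: str) -> bool:
    return str(chrom).removeprefix("chr") == "X"
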