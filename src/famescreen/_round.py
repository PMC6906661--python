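"""Half-up decimal rounding, used wherever printed-precision values are made."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(value: float, decimals: int) -> float:
    """Round to `decimals` places with ties going away from zero-adjacent
    halves upward (0.005 -> 0.01), not banker's rounding.

    Goes through repr() so that e.g. 2.675 (stored as 2.67499...) still
    rounds by its shortest decimal representation, matching how a human
    rounds a printed table value.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
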