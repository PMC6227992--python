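"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed reports).

    ``round_half_away(220.8333, 0) == 221``; ``round_half_away(79.166, 1) == 79.2``.
    """
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def samples_to_ms(n_samples: float, fs: float, decimals: int = 0) -> float:
    """Convert a sample count to milliseconds (``n / fs * 1000``), rounded.

    At 240 Hz: 53 samples -> 221 ms, 33 -> 138 ms, 28 -> 117 ms and, at
    one decimal, 19 -> 79.2 ms.
    """
    return round_half_away(n_samples / fs * 1000.0, decimals)
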