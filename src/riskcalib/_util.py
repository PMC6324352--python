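"""Small shared numeric helpers."""

from __future__ import annotations

import hashlib
import math
from pathlib import Path


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (5 always rounds up in magnitude).

    Python's built-in round() uses banker's rounding; published clinical
    tables conventionally round half away from zero, and every verifiable
    printed percentage in the reference tables is consistent with this rule.
    """
    if not math.isfinite(x):
        return x
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent(count: float, denominator: float, ndigits: int = 1) -> float:
    """Prevalence-style percentage, rounded half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round_half_away(100.0 * count / denominator, ndigits)


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
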