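"""Small shared numeric helpers."""

from __future__ import annotations

import math


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (39% not 38%)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent1(count: float, total: float) -> float:
    """Percentage to one decimal place, halves up (published-table style)."""
    if total == 0:
        return 0.0
    return math.floor(100.0 * count / total * 10 + 0.5) / 10
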