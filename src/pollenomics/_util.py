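"""Small shared helpers: report rounding and table validation."""

from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), as used in report tables.

    Python's built-in ``round`` is banker's rounding; report cells such as
    7.95% -> 8.0% need deterministic half-up behaviour.
    """
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    scaled = x * factor
    # nudge by one ulp-scale epsilon so values stored as 7.9499999999 from
    # decimal literals still round like their printed form
    eps = math.copysign(1e-9, scaled)
    return math.floor(abs(scaled) + 0.5 + abs(eps)) / factor * math.copysign(1.0, x) if x != 0 else 0.0


def require_columns(df, columns, name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing required columns: {missing}")
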