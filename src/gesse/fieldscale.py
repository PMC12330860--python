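"""Field-strength scaling of the R2 orientation-dependence range.

Compares the observed orientation-dependence range at the high field
against a reference range measured at a lower field, alongside the bare
ratio of field strengths; a near-match of the two ratios indicates
close-to-linear scaling of the orientation effect with B0.
"""

from __future__ import annotations

__all__ = ["field_scaling_report"]


def field_scaling_report(
    observed_range: float,
    reference_range: float = 2.2,
    b0_high: float = 7.0,
    b0_low: float = 3.0,
    ndigits: int = 2,
) -> dict:
    """Ratio of orientation-dependence ranges vs ratio of field strengths.

    ``observed_range`` is the high-field orientation-dependence range in
    s^-1 (the sin^4(alpha)-only slope); ``reference_range`` the low-field
    comparison value.  Both ratios are rounded to ``ndigits`` decimals.
    """
    if observed_range <= 0 or reference_range <= 0:
        raise ValueError("ranges must be positive")
    if b0_high <= 0 or b0_low <= 0:
        raise ValueError("field strengths must be positive")
    return {
        "observed_range": observed_range,
        "reference_range": reference_range,
        "range_ratio": round(observed_range / reference_range, ndigits),
        "field_ratio": round(b0_high / b0_low, ndigits),
        "b0_high": b0_high,
        "b0_low": b0_low,
    }
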