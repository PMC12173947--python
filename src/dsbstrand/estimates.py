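"""Back-of-envelope population arithmetic.

Bulk assays average over all genome copies in the population, so a
hybrid frequency measured on everything understates how often hybrids
form on the copies that are actually broken: only a minority of copies
is cleaved at any induced site.  Dividing the population-level hybrid
frequency by the cleaved fraction converts it to a per-damaged-copy
frequency (assuming damage-induced hybrids form only on cleaved copies).
"""

from __future__ import annotations

__all__ = ["per_damaged_copy_frequency", "per_damaged_copy_frequency_range"]


def per_damaged_copy_frequency(hybrid_fraction: float, cleaved_fraction: float) -> float:
    """Fraction of cleaved copies carrying a hybrid, as a percentage.

    ``hybrid_fraction`` is the population-level hybrid frequency (e.g.
    0.075 when 7.5% of all copies carry a hybrid) and ``cleaved_fraction``
    the fraction of copies cut at the site.  The result is capped at 100%.
    """
    if not 0 < cleaved_fraction <= 1:
        raise ValueError("cleaved_fraction must be in (0, 1]")
    if not 0 <= hybrid_fraction <= 1:
        raise ValueError("hybrid_fraction must be in [0, 1]")
    return min(100.0, 100.0 * hybrid_fraction / cleaved_fraction)


def per_damaged_copy_frequency_range(
    hybrid_range: tuple[float, float] = (0.05, 0.10),
    cleaved_range: tuple[float, float] = (0.10, 0.20),
) -> float:
    """Range-midpoint per-damaged-copy hybrid frequency, in percent.

    Defaults are the typical measured ranges for a strongly cleaved,
    hybrid-forming break: R-loop-level hybrid frequencies of 5–10% of all
    copies against cleavage in 10–20% of copies, giving ~50% of damaged
    copies carrying a hybrid.
    """
    h = 0.5 * (hybrid_range[0] + hybrid_range[1])
    c = 0.5 * (cleaved_range[0] + cleaved_range[1])
    return per_damaged_copy_frequency(h, c)
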