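"""Exact summary arithmetic: genome size from flow cytometry, mean feature
lengths, densities, percentages and marker spacing.

All functions are pure and exact on rational inputs.  Rounding is
half-away-from-zero throughout (``round_half_away``), not banker's rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FlowCytometryInput",
    "genome_size_bp",
    "mean_length",
    "percentage",
    "percent_change",
    "marker_spacing",
    "round_half_away",
    "round_sig",
]

#: Conversion between DNA mass and length: base pairs per picogram.
BP_PER_PG = 0.978e9


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero (2.5 -> 3, -2.5 -> -3)."""
    factor = 10.0 ** decimals
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / factor


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (half away from zero)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round_half_away(x, decimals=sig - 1 - exponent)


@dataclass(frozen=True)
class FlowCytometryInput:
    """2C nuclear DNA mass in picograms plus the pg->bp conversion factor."""

    mass_2c_pg: float
    bp_per_pg: float = BP_PER_PG

    def __post_init__(self):
        if self.mass_2c_pg <= 0:
            raise ValueError(f"2C mass must be positive, got {self.mass_2c_pg}")
        if self.bp_per_pg <= 0:
            raise ValueError(f"conversion factor must be positive, got {self.bp_per_pg}")


def genome_size_bp(fc: FlowCytometryInput) -> float:
    """1C genome size in bp: half the 2C mass times the pg->bp factor."""
    return (fc.mass_2c_pg / 2.0) * fc.bp_per_pg


def mean_length(total_bp: float, count: int) -> int:
    """Mean feature length in bp, rounded to the nearest integer."""
    if count <= 0:
        raise ValueError(f"count must be positive, got {count}")
    return int(round_half_away(total_bp / count))


def percentage(part: float, whole: float, decimals: int = 2) -> float:
    """100 * part / whole, rounded to ``decimals`` places."""
    if whole == 0:
        raise ValueError("whole must be nonzero")
    return round_half_away(100.0 * part / whole, decimals)


def percent_change(a: float, b: float) -> float:
    """Signed percent change of ``a`` relative to reference ``b``."""
    if b == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (a - b) / b


def marker_spacing(total_cm: float, n_markers: int, n_groups: int) -> float:
    """Mean inter-marker distance: total map length over marker intervals.

    The number of intervals on a map with ``n_markers`` markers in
    ``n_groups`` groups is ``n_markers - n_groups``.
    """
    if n_groups < 1:
        raise ValueError(f"need at least one group, got {n_groups}")
    if n_markers <= n_groups:
        raise ValueError(f"need more markers ({n_markers}) than groups ({n_groups})")
    return total_cm / (n_markers - n_groups)
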