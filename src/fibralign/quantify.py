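"""Cell-count comparison arithmetic.

Two culture conditions are compared from integer count pairs per condition:
the total number of cells in a counted volume (nuclear stain) and the number
of marker-positive cells among them (e.g. a neuronal lineage marker).  The
derived quantities are the marker-positive fraction per condition and three
fold-changes between conditions — of totals, of marker-positive counts, and
of the fractions themselves.  All printed values are rounded half-up to one
decimal, matching how such comparisons are conventionally reported; the fold
of fractions is always computed from the *unrounded* fractions first.

No inferential statistics are computed here: counts arrive as summaries, so
replicate-level information needed for a t-test is not available.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

from .errors import ParameterError


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties going away from zero, as in hand-rounded reports.

    Python's built-in ``round`` uses banker's rounding; count reports
    conventionally round 0.05 up, so the rule is centralised here.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CountSummary:
    """Cell counts for one condition.

    ``dispersion`` optionally stores the reported spread of each count
    (e.g. the "+/-" values of a mean); it is metadata only and enters no
    calculation.  ``region_dims_um`` documents the counted volume.
    """

    condition: str
    total_cells: int
    marker_positive: int
    region_dims_um: tuple[float, float, float] | None = None
    dispersion: tuple[float, float] | None = None

    def __post_init__(self):
        if self.total_cells <= 0:
            raise ParameterError(
                f"{self.condition!r}: total_cells must be positive, "
                f"got {self.total_cells}")
        if self.marker_positive < 0:
            raise ParameterError(
                f"{self.condition!r}: marker_positive must be non-negative")
        if self.marker_positive > self.total_cells:
            raise ParameterError(
                f"{self.condition!r}: marker_positive "
                f"({self.marker_positive}) exceeds total_cells "
                f"({self.total_cells})")


@dataclass(frozen=True)
class ComparisonReport:
    """Derived comparison of two conditions (a = reference, b = alternative)."""

    condition_a: str
    condition_b: str
    fraction_a_pct: float
    fraction_b_pct: float
    total_fold: float
    fraction_fold: float
    marker_fold: float

    def to_dict(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "fraction_a_pct": self.fraction_a_pct,
            "fraction_b_pct": self.fraction_b_pct,
            "total_fold": self.total_fold,
            "fraction_fold": self.fraction_fold,
            "marker_fold": self.marker_fold,
        }


def positive_fraction(c: CountSummary, decimals: int = 1) -> float:
    """Marker-positive percentage of a condition, rounded half-up."""
    if c.total_cells <= 0:
        raise ZeroDivisionError("total_cells must be positive")
    return round_half_up(100.0 * c.marker_positive / c.total_cells, decimals)


def fold_change(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Ratio numerator/denominator rounded half-up to ``decimals``."""
    if denominator <= 0:
        raise ZeroDivisionError("fold-change denominator must be positive")
    return round_half_up(numerator / denominator, decimals)


def compare_conditions(a: CountSummary, b: CountSummary,
                       decimals: int = 1) -> ComparisonReport:
    """Assemble fractions and fold-changes for b relative to a.

    The fraction fold is computed from the unrounded fractions (equivalently
    from the raw counts) and only then rounded, so it is consistent with the
    underlying data rather than with the two displayed percentages.
    """
    frac_a_raw = 100.0 * a.marker_positive / a.total_cells
    frac_b_raw = 100.0 * b.marker_positive / b.total_cells
    if frac_a_raw <= 0 or a.marker_positive <= 0:
        raise ZeroDivisionError(
            f"reference condition {a.condition!r} has no marker-positive "
            f"cells; fraction fold undefined")
    return ComparisonReport(
        condition_a=a.condition,
        condition_b=b.condition,
        fraction_a_pct=round_half_up(frac_a_raw, decimals),
        fraction_b_pct=round_half_up(frac_b_raw, decimals),
        total_fold=fold_change(b.total_cells, a.total_cells, decimals),
        fraction_fold=round_half_up(frac_b_raw / frac_a_raw, decimals),
        marker_fold=fold_change(b.marker_positive, a.marker_positive, decimals),
    )


def read_counts_csv(path) -> dict[str, CountSummary]:
    """Read a CSV with columns (condition, total_cells, marker_positive)."""
    df = pd.read_csv(Path(path))
    required = {"condition", "total_cells", "marker_positive"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"counts CSV missing columns: {sorted(missing)}")
    out: dict[str, CountSummary] = {}
    for _, row in df.iterrows():
        c = CountSummary(condition=str(row["condition"]),
                         total_cells=int(row["total_cells"]),
                         marker_positive=int(row["marker_positive"]))
        out[c.condition] = c
    return out
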