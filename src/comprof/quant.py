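"""Whole-lane and band-resolved complex subunit abundance ratios.

For a complex subunit, its abundance in a group is the sum of its
normalized ion intensities over the scope's gel slices (the whole lane or
one named band) pooled over all of the group's biological replicates.  The
ratio test/reference (mutant/wild-type) per subunit and its median over the
complex's detected subunits make up a ratio table.  A subunit undetected
(zero total) in either group yields the sentinel ``"nd"`` (not detected)
and is excluded from the median.

Medians use the even-n convention: the mean of the two central values of
the sorted list.  Reported values are rounded half-up to two decimals at
output only; all computation keeps full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .core import BandMap, ComplexCatalog, ComplexomeMatrix

__all__ = [
    "RatioEntry", "RatioTable",
    "total_abundance", "median_even_n", "round_half_up",
    "complex_ratio_table", "band_ratio_panel",
]

ALL_BANDS = "all-bands"
ND = "nd"


def total_abundance(
    matrix: ComplexomeMatrix,
    group: str,
    protein: str,
    scope: str = ALL_BANDS,
    bands: BandMap | None = None,
) -> float:
    """Summed intensity over a scope's slices and all of a group's replicates.

    *scope* is ``"all-bands"`` (every slice) or a band label resolved via
    *bands*.  Pooling replicates by summation matches reporting ratios from
    "summed ion intensities of three biological replicates"; any common
    replicate count cancels in the ratio.
    """
    vals = matrix.group_values(protein, group)  # (S, n_reps)
    if scope == ALL_BANDS:
        return float(vals.sum())
    if bands is None:
        raise ValueError(f"band scope {scope!r} requires a BandMap")
    idx = [k - 1 for k in bands.slices(scope)]
    for k in idx:
        if k >= matrix.n_slices:
            raise ValueError(f"band {scope!r} slice {k + 1} beyond gel of "
                             f"{matrix.n_slices} slices")
    return float(vals[idx, :].sum())


def median_even_n(values: Sequence[float]) -> float:
    """Median with the even-n convention (mean of the two central values)."""
    vals = sorted(float(v) for v in values)
    n = len(vals)
    if n == 0:
        raise ValueError("median of an empty list is undefined")
    mid = n // 2
    if n % 2:
        return vals[mid]
    return (vals[mid - 1] + vals[mid]) / 2.0


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up (so 0.985 -> 0.99), mirroring report tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RatioEntry:
    """One subunit's scoped totals and their b/a ratio (or ``"nd"``)."""

    protein: str
    subunit_class: str | None
    group_a_total: float
    group_b_total: float

    @property
    def ratio(self) -> float | str:
        if self.group_a_total <= 0 or self.group_b_total <= 0:
            return ND
        return self.group_b_total / self.group_a_total

    @property
    def defined(self) -> bool:
        return self.ratio != ND


@dataclass
class RatioTable:
    """Ratio entries for one complex in one scope, with their median."""

    complex: str
    scope: str
    group_a: str
    group_b: str
    entries: list[RatioEntry]
    missing_members: list[str]

    @property
    def median_ratio(self) -> float | None:
        defined = [e.ratio for e in self.entries if e.defined]
        if not defined:
            return None
        return median_even_n(defined)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with full-precision and two-decimal display columns."""
        rows = []
        for e in self.entries:
            r = e.ratio
            rows.append({
                "protein": e.protein,
                "subunit_class": e.subunit_class or "",
                f"total_{self.group_a}": e.group_a_total,
                f"total_{self.group_b}": e.group_b_total,
                "ratio": r if e.defined else math.nan,
                "ratio_display": f"{round_half_up(r):.2f}" if e.defined else ND,
            })
        med = self.median_ratio
        rows.append({
            "protein": "Median",
            "subunit_class": "",
            f"total_{self.group_a}": math.nan,
            f"total_{self.group_b}": math.nan,
            "ratio": med if med is not None else math.nan,
            "ratio_display": f"{round_half_up(med):.2f}" if med is not None else ND,
        })
        return pd.DataFrame(rows)


def complex_ratio_table(
    matrix: ComplexomeMatrix,
    catalog: ComplexCatalog,
    complex_name: str,
    group_a: str,
    group_b: str,
    scope: str = ALL_BANDS,
    bands: BandMap | None = None,
) -> RatioTable:
    """Per-subunit b/a abundance ratios for one complex in one scope.

    Members absent from the matrix are reported in ``missing_members`` and
    skipped.  The median is computed on unrounded defined ratios.
    """
    entries, missing = [], []
    for protein, cls in catalog.members(complex_name):
        if protein not in matrix.proteins:
            missing.append(protein)
            continue
        ta = total_abundance(matrix, group_a, protein, scope, bands)
        tb = total_abundance(matrix, group_b, protein, scope, bands)
        entries.append(RatioEntry(protein=protein, subunit_class=cls,
                                  group_a_total=ta, group_b_total=tb))
    return RatioTable(complex=complex_name, scope=scope, group_a=group_a,
                      group_b=group_b, entries=entries, missing_members=missing)


def band_ratio_panel(
    matrix: ComplexomeMatrix,
    catalog: ComplexCatalog,
    complex_name: str,
    group_a: str,
    group_b: str,
    bands: BandMap,
    band_labels: Sequence[str] | None = None,
) -> dict[str, RatioTable]:
    """One :class:`RatioTable` per band, shared member order across bands."""
    labels = list(band_labels) if band_labels is not None else bands.labels()
    return {lb: complex_ratio_table(matrix, catalog, complex_name, group_a,
                                    group_b, scope=lb, bands=bands)
            for lb in labels}
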