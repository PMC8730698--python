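"""Total-ion-intensity normalization and the proteotypic filter.

Lane loading differs between BN-PAGE replicates even when equal protein
amounts are loaded, so per-sample totals are equalized before any
comparison: each sample's correction factor is its total ion intensity
divided by the arithmetic mean of all samples' totals, and every intensity
is divided by its sample's factor.  Afterwards every per-sample total
equals the pre-normalization grand mean.

Normalization is applied to the full identified-protein matrix; proteins
identified only by non-proteotypic (shared) peptides are discarded
afterwards, since their intensities cannot be attributed unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import ComplexomeMatrix, ProteinAnnotation

__all__ = ["NormalizationResult", "sample_totals", "normalize", "filter_proteotypic"]


@dataclass
class NormalizationResult:
    """Outcome of total-ion-intensity normalization.

    ``factors[s] = pre_totals[s] / grand_mean``; dividing sample *s* by its
    factor equalizes all per-sample totals at ``grand_mean``.
    """

    factors: dict[str, float]
    normalized: ComplexomeMatrix
    pre_totals: dict[str, float]
    grand_mean: float


def sample_totals(matrix: ComplexomeMatrix) -> dict[str, float]:
    """Total ion intensity per sample: sum over all proteins and slices."""
    totals = matrix.values.sum(axis=(0, 1))
    return {s: float(totals[j]) for j, s in enumerate(matrix.design.samples)}


def normalize(matrix: ComplexomeMatrix) -> NormalizationResult:
    """Equalize per-sample total ion intensities.

    Raises
    ------
    ValueError
        If any sample has zero total intensity (its factor is undefined;
        an empty lane signals an upstream defect rather than biology).
    """
    pre = sample_totals(matrix)
    zero = [s for s, t in pre.items() if t <= 0]
    if zero:
        raise ValueError(f"zero total ion intensity in sample(s) {zero}; "
                         "correction factor undefined")
    grand_mean = float(np.mean(list(pre.values())))
    factors = {s: t / grand_mean for s, t in pre.items()}
    fac = np.array([factors[s] for s in matrix.design.samples])
    normalized = ComplexomeMatrix(matrix.proteins, matrix.n_slices, matrix.design,
                                  matrix.values / fac[np.newaxis, np.newaxis, :])
    return NormalizationResult(factors=factors, normalized=normalized,
                               pre_totals=pre, grand_mean=grand_mean)


def filter_proteotypic(
    matrix: ComplexomeMatrix,
    annotations: Mapping[str, ProteinAnnotation],
) -> ComplexomeMatrix:
    """Drop proteins not identified by at least one proteotypic peptide.

    Every matrix protein must be annotated; unannotated ids raise with the
    full offending list so the bundle can be fixed in one pass.
    """
    missing = [p for p in matrix.proteins if p not in annotations]
    if missing:
        raise ValueError(f"unannotated protein(s): {missing}")
    keep = [p for p in matrix.proteins if annotations[p].proteotypic]
    return matrix.subset(keep)
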