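"""Co-migration and band-enrichment screens for complex-associated proteins.

Two discovery procedures over a normalized complexome matrix:

*Co-migration screen.*  A candidate protein passes when it
(i) migrates like the canonical subunits of a reference complex in BOTH
groups — operationalized as Pearson correlation >= a threshold between the
candidate's max-scaled group-mean profile and a consensus profile built
from the reference subunits; (ii) was detected in at least ``min_replicates``
replicates in at least one group; (iii) carries a predicted chloroplast
transit peptide; and (iv) is conserved in photosynthetic organisms.
Criteria (iii)/(iv) are consumed as boolean annotations.

*Band-enrichment screen.*  A candidate passes when its summed intensity in
one named band (e.g. the RC47 band) is at least ``min_fold`` times higher
in the test group than in the reference group (infinite fold when absent
from the reference band but present in the test band), plus criteria
(ii)-(iv).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import BandMap, ComplexomeMatrix, ProteinAnnotation
from .profiles import detection_count, group_mean_profile, max_scale
from .quant import total_abundance

__all__ = [
    "ConsensusProfile", "ScreenCandidate",
    "consensus_profile", "profile_similarity",
    "screen_comigrating", "screen_band_enriched",
]

CRITERION_SIMILARITY = "i: profile resembles reference complex"
CRITERION_DETECTION = "ii: detected in >= min replicates in one group"
CRITERION_CTP = "iii: chloroplast transit peptide"
CRITERION_CONSERVED = "iv: conserved in photosynthetic organisms"
CRITERION_FOLD = "band: fold enrichment >= threshold"


@dataclass
class ConsensusProfile:
    """Mean of the max-scaled group-mean profiles of a complex's subunits."""

    group: str
    members_used: list[str]
    consensus: np.ndarray  # length S, entries in [0, 1]


def consensus_profile(matrix: ComplexomeMatrix, group: str,
                      member_ids: Sequence[str]) -> ConsensusProfile:
    """Build the reference migration shape from detected members.

    Members with an all-zero group-mean profile are excluded (and reported
    via ``members_used``); max-scaling each member first gives every subunit
    equal weight regardless of its absolute intensity.
    """
    used, scaled = [], []
    for pid in member_ids:
        mean = group_mean_profile(matrix, group, pid).mean
        if mean.max() > 0:
            used.append(pid)
            scaled.append(max_scale(mean))
    if not used:
        raise ValueError(f"no member of {list(member_ids)} detected in group {group!r}")
    return ConsensusProfile(group=group, members_used=used,
                            consensus=np.mean(scaled, axis=0))


def profile_similarity(candidate: np.ndarray, consensus: np.ndarray) -> float:
    """Pearson correlation between the max-scaled candidate and a consensus.

    Constant vectors have no defined correlation; by convention the
    similarity is then 0.  An all-zero candidate is an error (nothing to
    compare).
    """
    cand = np.asarray(candidate, dtype=float)
    cons = np.asarray(consensus, dtype=float)
    if cand.shape != cons.shape:
        raise ValueError("candidate and consensus must have equal length")
    if cand.max() <= 0:
        raise ValueError("all-zero candidate profile has no migration shape")
    cand = max_scale(cand)
    if np.ptp(cand) == 0 or np.ptp(cons) == 0:
        return 0.0
    return float(np.corrcoef(cand, cons)[0, 1])


@dataclass
class ScreenCandidate:
    """One protein's screen evaluation: criterion flags and overall verdict."""

    protein: str
    similarity_a: float = float("nan")
    similarity_b: float = float("nan")
    detection_a: int = 0
    detection_b: int = 0
    has_ctp: bool = False
    conserved: bool = False
    band_fold: float | None = None
    passes: dict[str, bool] = field(default_factory=dict)
    failure_reasons: list[str] = field(default_factory=list)

    @property
    def verdict(self) -> bool:
        return all(self.passes.values())


def _flag_criteria(cand: ScreenCandidate) -> None:
    cand.failure_reasons = [name for name, ok in cand.passes.items() if not ok]


def screen_comigrating(
    matrix: ComplexomeMatrix,
    annotations: Mapping[str, ProteinAnnotation],
    member_ids: Sequence[str],
    groups: tuple[str, str],
    min_similarity: float = 0.8,
    min_replicates: int = 2,
) -> tuple[list[ScreenCandidate], list[ScreenCandidate]]:
    """Four-criterion co-migration screen against a reference complex.

    Returns ``(candidates, diagnostics)``: candidates pass all four
    criteria, sorted by ``min(similarity_a, similarity_b)`` descending
    (ties by protein id); diagnostics holds every evaluated protein with
    per-criterion flags and failure reasons.
    """
    if not member_ids:
        raise ValueError("empty reference member set")
    group_a, group_b = groups
    cons_a = consensus_profile(matrix, group_a, member_ids)
    cons_b = consensus_profile(matrix, group_b, member_ids)
    members = set(member_ids)

    diagnostics: list[ScreenCandidate] = []
    for pid in matrix.proteins:
        if pid in members:
            continue
        ann = annotations.get(pid)
        cand = ScreenCandidate(
            protein=pid,
            detection_a=detection_count(matrix, group_a, pid),
            detection_b=detection_count(matrix, group_b, pid),
            has_ctp=bool(ann and ann.has_ctp),
            conserved=bool(ann and ann.conserved),
        )
        for group, cons, attr in ((group_a, cons_a, "similarity_a"),
                                  (group_b, cons_b, "similarity_b")):
            mean = group_mean_profile(matrix, group, pid).mean
            if mean.max() > 0:
                setattr(cand, attr, profile_similarity(mean, cons.consensus))
        sim_ok = (np.isfinite(cand.similarity_a) and np.isfinite(cand.similarity_b)
                  and cand.similarity_a >= min_similarity
                  and cand.similarity_b >= min_similarity)
        cand.passes = {
            CRITERION_SIMILARITY: bool(sim_ok),
            CRITERION_DETECTION: max(cand.detection_a, cand.detection_b) >= min_replicates,
            CRITERION_CTP: cand.has_ctp,
            CRITERION_CONSERVED: cand.conserved,
        }
        _flag_criteria(cand)
        diagnostics.append(cand)

    candidates = [c for c in diagnostics if c.verdict]
    candidates.sort(key=lambda c: (-min(c.similarity_a, c.similarity_b), c.protein))
    return candidates, diagnostics


def screen_band_enriched(
    matrix: ComplexomeMatrix,
    annotations: Mapping[str, ProteinAnnotation],
    band: str,
    bands: BandMap,
    groups: tuple[str, str],
    min_fold: float = 4.0,
    min_replicates: int = 2,
) -> tuple[list[ScreenCandidate], list[ScreenCandidate]]:
    """Screen for proteins accumulating in one band of the test group.

    ``band_fold`` = band total in group_b / band total in group_a; a
    protein absent from the reference band but present in the test band
    gets infinite fold and always passes the fold gate.  Candidates pass
    the fold gate plus criteria (ii)-(iv), sorted by fold descending.
    """
    if min_fold <= 1:
        raise ValueError("min_fold must exceed 1")
    group_a, group_b = groups
    bands.slices(band)  # raises on unknown band

    diagnostics: list[ScreenCandidate] = []
    for pid in matrix.proteins:
        ann = annotations.get(pid)
        ta = total_abundance(matrix, group_a, pid, scope=band, bands=bands)
        tb = total_abundance(matrix, group_b, pid, scope=band, bands=bands)
        if tb <= 0:
            fold = 0.0                     # nothing in the test band
        elif ta <= 0:
            fold = float("inf")            # nd in reference -> passes gate
        else:
            fold = tb / ta
        cand = ScreenCandidate(
            protein=pid,
            detection_a=detection_count(matrix, group_a, pid),
            detection_b=detection_count(matrix, group_b, pid),
            has_ctp=bool(ann and ann.has_ctp),
            conserved=bool(ann and ann.conserved),
            band_fold=fold,
        )
        cand.passes = {
            CRITERION_FOLD: fold >= min_fold,
            CRITERION_DETECTION: max(cand.detection_a, cand.detection_b) >= min_replicates,
            CRITERION_CTP: cand.has_ctp,
            CRITERION_CONSERVED: cand.conserved,
        }
        _flag_criteria(cand)
        diagnostics.append(cand)

    candidates = [c for c in diagnostics if c.verdict]
    candidates.sort(key=lambda c: (-c.band_fold, c.protein))
    return candidates, diagnostics
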