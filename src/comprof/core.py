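"""Core domain types for slice-resolved complexome profiling data.

A complexome profiling experiment slices a BN-PAGE lane into S gel slices
(slice 1 = top of the gel, largest apparent mass), digests each slice and
quantifies protein-group ion intensities per slice by LC-MS/MS.  The central
container here is :class:`ComplexomeMatrix`, a dense nonnegative tensor
indexed by (protein, slice, sample), together with a :class:`SampleDesign`
mapping samples to (group, replicate).  Missing values are stored as exact 0
— the convention of protein-group intensity exports — and "detected" is
defined downstream as nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SampleDesign",
    "ComplexomeMatrix",
    "ProteinAnnotation",
    "BandMap",
    "ComplexCatalog",
    "ValidationReport",
    "validate_bundle",
]


class SampleDesign:
    """Mapping of samples to experimental groups and replicate indices.

    Parameters
    ----------
    samples
        Ordered sample identifiers (the column order of the experiment).
    group_of
        sample -> group label (e.g. ``"WT"``, ``"lpa2"``).
    replicate_of
        sample -> 1-based replicate index within its group.
    """

    def __init__(
        self,
        samples: Sequence[str],
        group_of: Mapping[str, str],
        replicate_of: Mapping[str, int],
    ):
        samples = list(samples)
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample identifiers")
        if not samples:
            raise ValueError("design needs at least one sample")
        for s in samples:
            if s not in group_of:
                raise ValueError(f"sample {s!r} has no group")
            if s not in replicate_of:
                raise ValueError(f"sample {s!r} has no replicate index")
        pairs = [(group_of[s], replicate_of[s]) for s in samples]
        if len(set(pairs)) != len(pairs):
            raise ValueError("(group, replicate) pairs must be unique")
        self.samples: list[str] = samples
        self.group_of: dict[str, str] = {s: group_of[s] for s in samples}
        self.replicate_of: dict[str, int] = {s: int(replicate_of[s]) for s in samples}

    @property
    def groups(self) -> list[str]:
        """Distinct group labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.group_of[s], None)
        return list(seen)

    def samples_of(self, group: str) -> list[str]:
        """Samples belonging to *group*, ordered by replicate index."""
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        members = [s for s in self.samples if self.group_of[s] == group]
        return sorted(members, key=lambda s: self.replicate_of[s])

    @classmethod
    def from_groups(cls, groups: Mapping[str, int], sep: str = "_r") -> "SampleDesign":
        """Build a design from group -> replicate-count, naming samples
        ``<group><sep><replicate>`` (e.g. ``WT_r1``)."""
        samples, g, r = [], {}, {}
        for group, n in groups.items():
            for i in range(1, int(n) + 1):
                s = f"{group}{sep}{i}"
                samples.append(s)
                g[s] = group
                r[s] = i
        return cls(samples, g, r)

    @classmethod
    def infer(cls, samples: Sequence[str]) -> "SampleDesign":
        """Infer a design from sample names of the form ``<group>_<rep>``
        (the replicate index is the trailing integer after the last ``_``,
        with an optional ``r`` prefix, e.g. ``WT_1`` or ``lpa2_r3``)."""
        g, r = {}, {}
        for s in samples:
            head, _, tail = s.rpartition("_")
            tail = tail.lstrip("rR")
            if not head or not tail.isdigit():
                raise ValueError(
                    f"cannot infer group/replicate from sample name {s!r}; "
                    "expected '<group>_<replicate>'"
                )
            g[s] = head
            r[s] = int(tail)
        return cls(samples, g, r)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SampleDesign)
            and self.samples == other.samples
            and self.group_of == other.group_of
            and self.replicate_of == other.replicate_of
        )

    def __repr__(self) -> str:
        return f"SampleDesign({len(self.samples)} samples, groups={self.groups})"


class ComplexomeMatrix:
    """Dense (protein, slice, sample) intensity tensor.

    Intensities are nonnegative finite reals in arbitrary ion-intensity
    units; a stored 0 means "not detected".  Slice indices are 1-based from
    the top of the gel so that band numbers match gel annotation directly.
    """

    def __init__(self, proteins: Sequence[str], n_slices: int, design: SampleDesign,
                 values: np.ndarray):
        proteins = list(proteins)
        if len(set(proteins)) != len(proteins):
            raise ValueError("duplicate protein identifiers")
        values = np.asarray(values, dtype=float)
        expected = (len(proteins), int(n_slices), len(design.samples))
        if values.shape != expected:
            raise ValueError(f"values shape {values.shape} != {expected}")
        if not np.all(np.isfinite(values)):
            raise ValueError("intensities must be finite")
        if np.any(values < 0):
            raise ValueError("intensities must be nonnegative")
        self.proteins = proteins
        self.n_slices = int(n_slices)
        self.design = design
        self.values = values
        self._pidx = {p: i for i, p in enumerate(proteins)}
        self._sidx = {s: i for i, s in enumerate(design.samples)}

    # -- indexing -----------------------------------------------------------
    def protein_index(self, protein: str) -> int:
        try:
            return self._pidx[protein]
        except KeyError:
            raise KeyError(f"unknown protein {protein!r}") from None

    def sample_index(self, sample: str) -> int:
        try:
            return self._sidx[sample]
        except KeyError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def intensity(self, protein: str, slice_: int, sample: str) -> float:
        """Single-cell lookup; *slice_* is 1-based."""
        if not 1 <= slice_ <= self.n_slices:
            raise IndexError(f"slice {slice_} out of range 1..{self.n_slices}")
        return float(self.values[self.protein_index(protein), slice_ - 1,
                                 self.sample_index(sample)])

    def profile(self, protein: str, sample: str) -> np.ndarray:
        """Per-slice intensity vector of one protein in one sample."""
        return self.values[self.protein_index(protein), :, self.sample_index(sample)].copy()

    def group_values(self, protein: str, group: str) -> np.ndarray:
        """(S, n_replicates) array for one protein across a group's samples."""
        cols = [self.sample_index(s) for s in self.design.samples_of(group)]
        return self.values[self.protein_index(protein)][:, cols]

    # -- manipulation -------------------------------------------------------
    def copy(self) -> "ComplexomeMatrix":
        return ComplexomeMatrix(self.proteins, self.n_slices, self.design,
                                self.values.copy())

    def subset(self, proteins: Iterable[str]) -> "ComplexomeMatrix":
        """Restrict to the given proteins (kept in current matrix order)."""
        keep = set(proteins)
        missing = keep - set(self.proteins)
        if missing:
            raise KeyError(f"unknown proteins: {sorted(missing)}")
        idx = [i for i, p in enumerate(self.proteins) if p in keep]
        return ComplexomeMatrix([self.proteins[i] for i in idx], self.n_slices,
                                self.design, self.values[idx])

    def __repr__(self) -> str:
        return (f"ComplexomeMatrix({len(self.proteins)} proteins x "
                f"{self.n_slices} slices x {len(self.design.samples)} samples)")


@dataclass(frozen=True)
class ProteinAnnotation:
    """Per-protein annotation consumed by the filters and screens.

    ``proteotypic``: identified by at least one proteotypic peptide;
    ``has_ctp``: predicted chloroplast transit peptide; ``conserved``:
    conserved in photosynthetic organisms.  The transit-peptide and
    conservation calls are consumed as boolean flags, not predicted here.
    """

    protein: str
    description: str = ""
    proteotypic: bool = True
    has_ctp: bool = False
    conserved: bool = False
    complex: str | None = None
    subunit_class: str | None = None

    VALID_CLASSES = ("core", "antenna", "oec", "auxiliary", "other")

    def __post_init__(self):
        if self.subunit_class is not None and self.subunit_class not in self.VALID_CLASSES:
            raise ValueError(
                f"subunit_class {self.subunit_class!r} not in {self.VALID_CLASSES}")


class BandMap:
    """Named gel bands: band label -> set of contiguous 1-based slice indices.

    In the study's gel, band 4 holds PSII supercomplexes, band 10 dimers,
    band 15 monomers and band 17 the RC47 assembly intermediate.
    """

    def __init__(self, bands: Mapping[str, Iterable[int]]):
        self.bands: dict[str, tuple[int, ...]] = {}
        for label, slices in bands.items():
            ss = tuple(sorted(int(k) for k in slices))
            if not ss:
                raise ValueError(f"band {label!r} has no slices")
            if any(k < 1 for k in ss):
                raise ValueError(f"band {label!r} has slice index < 1")
            if ss != tuple(range(ss[0], ss[-1] + 1)):
                raise ValueError(f"band {label!r} slices are not contiguous")
            if label in self.bands:
                raise ValueError(f"duplicate band label {label!r}")
            self.bands[label] = ss

    def slices(self, label: str) -> tuple[int, ...]:
        try:
            return self.bands[label]
        except KeyError:
            raise KeyError(f"unknown band {label!r}") from None

    def labels(self) -> list[str]:
        return list(self.bands)

    def check_range(self, n_slices: int) -> list[str]:
        """Band labels whose slices exceed 1..n_slices."""
        return [lb for lb, ss in self.bands.items() if ss[-1] > n_slices]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BandMap) and self.bands == other.bands

    def __repr__(self) -> str:
        return f"BandMap({self.bands})"


class ComplexCatalog:
    """Named protein complexes with ordered member subunits.

    ``complexes`` maps a complex name to an ordered list of
    ``(protein id, subunit_class)`` pairs.
    """

    def __init__(self, complexes: Mapping[str, Sequence[tuple[str, str | None]]]):
        self.complexes: dict[str, list[tuple[str, str | None]]] = {}
        for name, members in complexes.items():
            members = [(str(p), c) for p, c in members]
            if not members:
                raise ValueError(f"complex {name!r} has no members")
            ids = [p for p, _ in members]
            if len(set(ids)) != len(ids):
                raise ValueError(f"complex {name!r} has duplicate members")
            self.complexes[name] = members

    def members(self, name: str) -> list[tuple[str, str | None]]:
        try:
            return list(self.complexes[name])
        except KeyError:
            raise KeyError(f"unknown complex {name!r}") from None

    def member_ids(self, name: str) -> list[str]:
        return [p for p, _ in self.members(name)]

    def names(self) -> list[str]:
        return list(self.complexes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ComplexCatalog) and self.complexes == other.complexes


@dataclass
class ValidationReport:
    """Consistency report across a loaded data bundle (report-only)."""

    unannotated_proteins: list[str] = field(default_factory=list)
    missing_members: list[tuple[str, str]] = field(default_factory=list)  # (complex, protein)
    bands_out_of_range: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.unannotated_proteins or self.missing_members
                    or self.bands_out_of_range)

    def messages(self) -> list[str]:
        out = []
        for p in self.unannotated_proteins:
            out.append(f"protein {p!r} in matrix lacks an annotation")
        for cx, p in self.missing_members:
            out.append(f"complex {cx!r} member {p!r} absent from matrix")
        for lb in self.bands_out_of_range:
            out.append(f"band {lb!r} references slices beyond the gel")
        return out


def validate_bundle(
    matrix: ComplexomeMatrix,
    annotations: Mapping[str, ProteinAnnotation] | None = None,
    catalog: ComplexCatalog | None = None,
    bands: BandMap | None = None,
) -> ValidationReport:
    """Cross-check a matrix against annotations, catalog and band map.

    Never raises; returns a :class:`ValidationReport` which is empty iff the
    bundle is fully consistent.
    """
    report = ValidationReport()
    if annotations is not None:
        report.unannotated_proteins = [p for p in matrix.proteins if p not in annotations]
    if catalog is not None:
        present = set(matrix.proteins)
        for name in catalog.names():
            for p in catalog.member_ids(name):
                if p not in present:
                    report.missing_members.append((name, p))
    if bands is not None:
        report.bands_out_of_range = bands.check_range(matrix.n_slices)
    return report
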