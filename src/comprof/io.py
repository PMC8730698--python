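"""Tab-separated readers and writers for complexome data bundles.

All files are UTF-8, Unix-newline TSV.

Intensity table dialects
------------------------
``wide``
    One row per protein; first column ``protein``; one column per
    (sample, slice) cell named ``<sample>|slice<k>`` with k = 1..S.  Blank
    or absent cells read as 0.
``mapped``
    A proteinGroups.txt-style export whose per-slice intensity columns are
    declared in a separate column-mapping TSV with columns
    ``column, sample, slice``.  This decouples the pipeline from any one
    search engine's column naming.

Annotations
-----------
Columns ``protein, description, proteotypic, has_ctp, conserved, complex,
subunit_class``; booleans encoded as 0/1 (also accepts true/false,
yes/no); empty ``complex``/``subunit_class`` mean unset.

Band maps are ``band, slices`` with slices either a single index ``17`` or
an inclusive range ``4-6``.  Catalogs are ``complex, protein,
subunit_class`` rows, one per member, member order = row order.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import BandMap, ComplexCatalog, ComplexomeMatrix, ProteinAnnotation, SampleDesign

__all__ = [
    "read_intensity_table", "write_intensity_table",
    "read_annotations", "write_annotations",
    "read_band_map", "write_band_map",
    "read_catalog", "write_catalog",
    "read_design", "write_design",
]

_WIDE_COL = re.compile(r"^(?P<sample>.+)\|slice(?P<slice>\d+)$")

_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f"}


class ParseError(ValueError):
    """Raised on malformed input files."""


def _parse_bool(value: str, column: str, row: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ParseError(f"row {row!r}: unknown boolean {value!r} in column {column!r}")


# ---------------------------------------------------------------------------
# intensity matrix
# ---------------------------------------------------------------------------

def read_intensity_table(
    path: str | Path,
    dialect: str = "wide",
    design: SampleDesign | None = None,
    mapping: str | Path | None = None,
) -> ComplexomeMatrix:
    """Read a protein x (sample, slice) intensity table.

    If *design* is omitted it is inferred from sample names of the form
    ``<group>_<replicate>``.  Absent/blank cells become 0; every sample must
    cover the same slice count.
    """
    path = Path(path)
    if dialect == "wide":
        df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
        if df.columns[0] != "protein":
            raise ParseError(f"{path}: first column must be 'protein', got {df.columns[0]!r}")
        cells: dict[str, dict[int, str]] = {}
        for col in df.columns[1:]:
            m = _WIDE_COL.match(col)
            if not m:
                raise ParseError(f"{path}: malformed intensity column {col!r} "
                                 "(expected '<sample>|slice<k>')")
            cells.setdefault(m["sample"], {})[int(m["slice"])] = col
    elif dialect == "mapped":
        if mapping is None:
            raise ParseError("dialect 'mapped' requires a column-mapping file")
        mp = pd.read_csv(mapping, sep="\t", dtype=str)
        for c in ("column", "sample", "slice"):
            if c not in mp.columns:
                raise ParseError(f"{mapping}: column-mapping file lacks column {c!r}")
        df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
        if df.columns[0] != "protein":
            raise ParseError(f"{path}: first column must be 'protein', got {df.columns[0]!r}")
        cells = {}
        for _, r in mp.iterrows():
            if r["column"] not in df.columns:
                raise ParseError(f"{path}: mapped column {r['column']!r} absent from table")
            cells.setdefault(r["sample"], {})[int(r["slice"])] = r["column"]
    else:
        raise ParseError(f"unknown intensity-table dialect {dialect!r}")

    if not cells:
        raise ParseError(f"{path}: no intensity columns found")
    slice_counts = {s: max(ks) for s, ks in cells.items()}
    counts = sorted(set(slice_counts.values()))
    if len(counts) > 1:
        detail = ", ".join(f"{s}={slice_counts[s]}" for s in sorted(slice_counts))
        raise ParseError(f"{path}: samples disagree on slice count ({detail})")
    n_slices = counts[0]

    proteins = df["protein"].tolist()
    if design is None:
        design = SampleDesign.infer(list(cells))
    values = np.zeros((len(proteins), n_slices, len(design.samples)))
    for j, sample in enumerate(design.samples):
        if sample not in cells:
            raise ParseError(f"{path}: design sample {sample!r} absent from table")
        for k, col in cells[sample].items():
            v = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            v = np.nan_to_num(v, nan=0.0)
            if np.any(v < 0):
                bad = proteins[int(np.argmin(v))]
                raise ParseError(f"{path}: negative intensity for protein {bad!r} "
                                 f"in column {col!r}")
            values[:, k - 1, j] = v
    return ComplexomeMatrix(proteins, n_slices, design, values)


def write_intensity_table(matrix: ComplexomeMatrix, path: str | Path) -> None:
    """Write a matrix in the ``wide`` dialect (full precision, repr-exact)."""
    cols = {"protein": matrix.proteins}
    for j, sample in enumerate(matrix.design.samples):
        for k in range(1, matrix.n_slices + 1):
            cols[f"{sample}|slice{k}"] = matrix.values[:, k - 1, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, lineterminator="\n",
                              float_format="%.17g")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_ANN_REQUIRED = ("protein", "description", "proteotypic", "has_ctp", "conserved")
_ANN_OPTIONAL = ("complex", "subunit_class")


def read_annotations(path: str | Path) -> dict[str, ProteinAnnotation]:
    """Read per-protein annotations keyed by protein id."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for c in _ANN_REQUIRED:
        if c not in df.columns:
            raise ParseError(f"{path}: missing mandatory column {c!r}")
    out: dict[str, ProteinAnnotation] = {}
    for _, r in df.iterrows():
        pid = r["protein"]
        if pid in out:
            raise ParseError(f"{path}: duplicate protein id {pid!r}")
        ann = ProteinAnnotation(
            protein=pid,
            description=r["description"],
            proteotypic=_parse_bool(r["proteotypic"], "proteotypic", pid),
            has_ctp=_parse_bool(r["has_ctp"], "has_ctp", pid),
            conserved=_parse_bool(r["conserved"], "conserved", pid),
            complex=(r.get("complex") or None) if "complex" in df.columns else None,
            subunit_class=(r.get("subunit_class") or None)
            if "subunit_class" in df.columns else None,
        )
        out[pid] = ann
    return out


def write_annotations(annotations: Mapping[str, ProteinAnnotation],
                      path: str | Path) -> None:
    rows = []
    for ann in annotations.values():
        rows.append({
            "protein": ann.protein,
            "description": ann.description,
            "proteotypic": int(ann.proteotypic),
            "has_ctp": int(ann.has_ctp),
            "conserved": int(ann.conserved),
            "complex": ann.complex or "",
            "subunit_class": ann.subunit_class or "",
        })
    pd.DataFrame(rows, columns=list(_ANN_REQUIRED) + list(_ANN_OPTIONAL)).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# band maps, catalogs, designs
# ---------------------------------------------------------------------------

def read_band_map(path: str | Path) -> BandMap:
    path = Path(path)
    bands: dict[str, list[int]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"band", "slices"} <= set(reader.fieldnames):
            raise ParseError(f"{path}: band map needs columns 'band' and 'slices'")
        for row in reader:
            label = row["band"]
            if label in bands:
                raise ParseError(f"{path}: duplicate band label {label!r}")
            spec = row["slices"].strip()
            if "-" in spec:
                lo, hi = spec.split("-", 1)
                bands[label] = list(range(int(lo), int(hi) + 1))
            else:
                bands[label] = [int(spec)]
    return BandMap(bands)


def write_band_map(bands: BandMap, path: str | Path) -> None:
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write("band\tslices\n")
        for label, ss in bands.bands.items():
            spec = str(ss[0]) if len(ss) == 1 else f"{ss[0]}-{ss[-1]}"
            fh.write(f"{label}\t{spec}\n")


def read_catalog(path: str | Path) -> ComplexCatalog:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for c in ("complex", "protein"):
        if c not in df.columns:
            raise ParseError(f"{path}: catalog needs columns 'complex' and 'protein'")
    complexes: dict[str, list[tuple[str, str | None]]] = {}
    for _, r in df.iterrows():
        cls = (r.get("subunit_class") or None) if "subunit_class" in df.columns else None
        complexes.setdefault(r["complex"], []).append((r["protein"], cls))
    return ComplexCatalog(complexes)


def write_catalog(catalog: ComplexCatalog, path: str | Path) -> None:
    rows = [{"complex": name, "protein": p, "subunit_class": c or ""}
            for name in catalog.names() for p, c in catalog.members(name)]
    pd.DataFrame(rows, columns=["complex", "protein", "subunit_class"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def read_design(path: str | Path) -> SampleDesign:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for c in ("sample", "group", "replicate"):
        if c not in df.columns:
            raise ParseError(f"{path}: design needs columns 'sample', 'group', 'replicate'")
    return SampleDesign(
        df["sample"].tolist(),
        dict(zip(df["sample"], df["group"])),
        {s: int(r) for s, r in zip(df["sample"], df["replicate"])},
    )


def write_design(design: SampleDesign, path: str | Path) -> None:
    rows = [{"sample": s, "group": design.group_of[s],
             "replicate": design.replicate_of[s]} for s in design.samples]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
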