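"""Pipeline orchestration and report rendering.

:func:`run_full_pipeline` ties the stages together in the analysis order
normalize -> proteotypic filter -> profiles -> differential statistics ->
ratio tables -> screens, writes every tabular output, and records a run
manifest (parameters, input checksums, package versions) sufficient to
reproduce all numeric outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import BandMap, ComplexCatalog, validate_bundle
from .io import (read_annotations, read_band_map, read_catalog, read_design,
                 read_intensity_table, write_intensity_table)
from .normalize import filter_proteotypic, normalize
from .profiles import DifferentialAbundanceModel, cluster_order, max_scale
from .quant import band_ratio_panel, complex_ratio_table
from .screen import screen_band_enriched, screen_comigrating

__all__ = ["PipelineConfig", "run_full_pipeline", "render_heatmap"]

log = logging.getLogger("comprof")


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs.

    Thresholds: ``min_similarity`` in [-1, 1], ``min_fold`` > 1,
    ``min_replicates`` >= 1.  ``screen_members`` may be a catalog complex
    name or an explicit protein id list.
    """

    intensity_path: str | Path
    annotation_path: str | Path
    output_dir: str | Path
    group_a: str = "WT"
    group_b: str = "lpa2"
    catalog_path: str | Path | None = None
    band_map_path: str | Path | None = None
    design_path: str | Path | None = None
    screen_members: list[str] | str | None = None
    screen_band: str | None = None
    min_similarity: float = 0.8
    min_fold: float = 4.0
    min_replicates: int = 2
    proteotypic_filter: bool = True
    heatmap: bool = False
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        for label, p in (("intensity", self.intensity_path),
                         ("annotation", self.annotation_path),
                         ("catalog", self.catalog_path),
                         ("band map", self.band_map_path),
                         ("design", self.design_path)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if not -1 <= self.min_similarity <= 1:
            raise ValueError("min_similarity must lie in [-1, 1]")
        if self.min_fold <= 1:
            raise ValueError("min_fold must exceed 1")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _candidates_frame(cands) -> pd.DataFrame:
    rows = []
    for c in cands:
        rows.append({
            "protein": c.protein,
            "similarity_a": c.similarity_a, "similarity_b": c.similarity_b,
            "detection_a": c.detection_a, "detection_b": c.detection_b,
            "has_ctp": int(c.has_ctp), "conserved": int(c.conserved),
            "band_fold": "" if c.band_fold is None else c.band_fold,
            "verdict": int(c.verdict),
            "failure_reasons": "; ".join(c.failure_reasons),
        })
    return pd.DataFrame(rows)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all outputs; returns the run manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, lineterminator="\n",
                  float_format="%.17g")
        written.append(name)

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("load")
        design = read_design(config.design_path) if config.design_path else None
        matrix = read_intensity_table(config.intensity_path, design=design)
        annotations = read_annotations(config.annotation_path)
        catalog = read_catalog(config.catalog_path) if config.catalog_path else None
        bands = read_band_map(config.band_map_path) if config.band_map_path else None
        report = validate_bundle(matrix, annotations, catalog, bands)
        for msg in report.messages():
            log.warning("bundle: %s", msg)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    try:
        stage("normalize")
        norm = normalize(matrix)
        write_intensity_table(norm.normalized, out / "normalized.tsv")
        written.append("normalized.tsv")
        emit(pd.DataFrame({"sample": list(norm.factors),
                           "pre_total": [norm.pre_totals[s] for s in norm.factors],
                           "factor": list(norm.factors.values())}),
             "normalization_factors.tsv")
        working = (filter_proteotypic(norm.normalized, annotations)
                   if config.proteotypic_filter else norm.normalized)
    except Exception as exc:
        raise RuntimeError(f"stage 'normalize' failed: {exc}") from exc

    try:
        stage("profiles+differential")
        model = DifferentialAbundanceModel(working, config.group_a, config.group_b)
        results = model.fit()
        emit(results.profiles_frame(), "profiles.tsv")
        emit(results.frame.reset_index(), "differential.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'profiles' failed: {exc}") from exc

    try:
        stage("ratio tables")
        if catalog is not None:
            for name in catalog.names():
                tbl = complex_ratio_table(working, catalog, name,
                                          config.group_a, config.group_b)
                emit(tbl.to_frame(), f"ratios_{name}_all-bands.tsv")
                if bands is not None:
                    panel = band_ratio_panel(working, catalog, name,
                                             config.group_a, config.group_b, bands)
                    for lb, bt in panel.items():
                        emit(bt.to_frame(), f"ratios_{name}_band-{lb}.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'ratio tables' failed: {exc}") from exc

    try:
        stage("screens")
        members = config.screen_members
        if isinstance(members, str):
            if catalog is None:
                raise ValueError("screen_members names a complex but no catalog given")
            members = catalog.member_ids(members)
        if members:
            cands, diag = screen_comigrating(
                working, annotations, members,
                (config.group_a, config.group_b),
                min_similarity=config.min_similarity,
                min_replicates=config.min_replicates)
            emit(_candidates_frame(cands), "screen_comigration_candidates.tsv")
            emit(_candidates_frame(diag), "screen_comigration_diagnostics.tsv")
        if config.screen_band:
            if bands is None:
                raise ValueError("screen_band set but no band map given")
            cands, diag = screen_band_enriched(
                working, annotations, config.screen_band, bands,
                (config.group_a, config.group_b),
                min_fold=config.min_fold,
                min_replicates=config.min_replicates)
            emit(_candidates_frame(cands), "screen_band_candidates.tsv")
            emit(_candidates_frame(diag), "screen_band_diagnostics.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'screens' failed: {exc}") from exc

    if config.heatmap:
        try:
            stage("heatmap")
            mat = {p: max_scale(results.group_profile(p, config.group_a).mean)
                   for p in working.proteins}
            frame = pd.DataFrame(mat).T
            frame.columns = [f"slice{k + 1}" for k in range(working.n_slices)]
            order = cluster_order(frame)
            render_heatmap(frame, order, out / "heatmap.png")
            written += ["heatmap.png", "heatmap.tsv"]
        except Exception as exc:
            raise RuntimeError(f"stage 'heatmap' failed: {exc}") from exc

    manifest = {
        "comprof_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "inputs": {
            str(k): {"path": str(v), "sha256": _sha256(v)}
            for k, v in (("intensity", config.intensity_path),
                         ("annotations", config.annotation_path),
                         ("catalog", config.catalog_path),
                         ("band_map", config.band_map_path),
                         ("design", config.design_path))
            if v is not None
        },
        "parameters": {
            "group_a": config.group_a, "group_b": config.group_b,
            "min_similarity": config.min_similarity,
            "min_fold": config.min_fold,
            "min_replicates": config.min_replicates,
            "proteotypic_filter": config.proteotypic_filter,
        },
        "outputs": written,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def render_heatmap(profiles: pd.DataFrame, order: list[str],
                   path: str | Path) -> Path:
    """Render a migration heat map (rows max-scaled) plus a sidecar TSV.

    *profiles* holds one row per protein (index = protein id), one column
    per slice; rows are max-scaled before plotting.  The sidecar TSV next
    to the image contains the exact plotted matrix.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if profiles.empty:
        raise ValueError("no profiles to render")
    scaled = profiles.loc[order].apply(lambda r: pd.Series(max_scale(r.to_numpy()),
                                                           index=profiles.columns),
                                       axis=1)
    path = Path(path)
    sidecar = path.with_suffix(".tsv")
    scaled.rename_axis("protein").to_csv(sidecar, sep="\t", lineterminator="\n",
                                         float_format="%.17g")

    fig, ax = plt.subplots(figsize=(8, max(2.0, 0.25 * len(order))))
    ax.imshow(scaled.to_numpy(), aspect="auto", cmap="viridis",
              interpolation="nearest", vmin=0, vmax=1)
    ax.set_yticks(range(len(order)), labels=order, fontsize=6)
    ax.set_xlabel("gel slice (top → bottom)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
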