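"""Batch orchestration: cohorts → animals → sections → fields.

Input grouping is encoded in a manifest CSV rather than directory layout,
so every output row is traceable.  Each run emits tidy CSVs plus a JSON
:class:`RunManifest` capturing the config snapshot, input checksums, and
warnings.  Given identical inputs, config and seed, outputs are
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import QuantConfig
from .diffuseness import diffuseness_pipeline
from .genesets import compare_gene_sets, read_gmt, score_gene_sets
from .io import read_expression, read_groups, read_multichannel, read_stack, read_image
from .microenv import (
    constrained_dilation,
    percent_area,
    plaque_associated_fraction,
    section_fraction,
    watershed_partition,
)
from .segmentation import segment_fluorescence, tissue_mask
from .coloc import manders

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_costain", "run_diffuseness", "run_coloc", "run_modules"]

#: channel → normalization mode for plaque-associated fractions
CHANNEL_MODES = {
    "Lamp1": "ring-normalized",
    "Iba1": "ring-normalized",
    "ApoE": "plaque-normalized",
}


@dataclass
class RunManifest:
    """Provenance record written next to every batch output."""

    config: dict
    inputs: list[dict] = field(default_factory=list)
    version: str = __version__
    timings_s: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add_input(self, path) -> None:
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None
        self.inputs.append({"path": str(p), "sha256": digest})

    def warn(self, msg: str) -> None:
        logger.warning(msg)
        self.warnings.append(msg)

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "version": self.version,
                    "config": self.config,
                    "inputs": self.inputs,
                    "timings_s": self.timings_s,
                    "warnings": self.warnings,
                },
                indent=2,
                default=str,
            )
            + "\n"
        )


def _timed(manifest: RunManifest, stage: str, t0: float) -> None:
    manifest.timings_s[stage] = round(time.perf_counter() - t0, 3)


def run_costain(
    config: QuantConfig, manifest_df: pd.DataFrame, base_dir=None
) -> tuple[dict[str, pd.DataFrame], RunManifest]:
    """Costain quantification over a cohort manifest.

    ``manifest_df`` needs columns ``animal``, ``section``, ``field``,
    ``image`` (path to a multi-channel TIFF whose sidecar names channels).
    Fields missing a channel are skipped for that channel's outputs only.
    Returns per-plaque, per-section and per-animal tables plus the run
    manifest.
    """
    if manifest_df.empty:
        raise ValueError("empty cohort: manifest has no rows")
    base = Path(base_dir) if base_dir else Path(".")
    run = RunManifest(config=config.to_dict())
    t0 = time.perf_counter()
    plaque_rows: list[pd.DataFrame] = []
    section_rows: list[dict] = []
    for _, row in manifest_df.iterrows():
        path = base / row["image"]
        run.add_input(path)
        channels = read_multichannel(path, pixel_size_um=config.pixel_size_um)
        if "X04" not in channels:
            run.warn(f"field {row['field']}: no X04 channel, skipped entirely")
            continue
        plaques, ptable = segment_fluorescence(
            channels["X04"],
            tophat_radius_um=config.tophat_radius_um,
            local_window_um=config.local_window_um,
            local_offset=config.local_offset,
            min_size_um2=config.min_size_um2,
            shape_limits=config.shape_limits,
        )
        partition = watershed_partition(plaques)
        rings = constrained_dilation(plaques, partition, config.dilation_radius_um)
        tissue = tissue_mask(channels["Iba1"]) if "Iba1" in channels else None
        for channel, mode in CHANNEL_MODES.items():
            if channel not in channels:
                run.warn(f"field {row['field']}: no {channel} channel, skipped for {channel}")
                continue
            limits = config.shape_limits if channel == "Lamp1" else None
            seg, _ = segment_fluorescence(
                channels[channel],
                tophat_radius_um=config.tophat_radius_um,
                local_window_um=config.local_window_um,
                local_offset=config.local_offset,
                min_size_um2=config.min_size_um2,
                shape_limits=limits,
            )
            signal = seg.mask()
            tab = plaque_associated_fraction(signal, plaques, rings, mode)
            tab.insert(0, "channel", channel)
            for key in ("animal", "section", "field"):
                tab.insert(0, key, row[key])
            plaque_rows.append(tab)
            rec = {
                "animal": row["animal"],
                "section": row["section"],
                "field": row["field"],
                "channel": channel,
                "fraction": section_fraction(tab, how=config.aggregation),
                "n_plaques": len(tab),
            }
            if tissue is not None and tissue.data.any():
                rec["percent_area"] = percent_area(signal, tissue)
            section_rows.append(rec)
    _timed(run, "costain", t0)
    per_plaque = (
        pd.concat(plaque_rows, ignore_index=True) if plaque_rows else pd.DataFrame()
    )
    per_field = pd.DataFrame(section_rows)
    if per_field.empty:
        raise ValueError("empty cohort: no field produced output")
    per_section = (
        per_field.groupby(["animal", "section", "channel"], as_index=False)
        .agg(fraction=("fraction", "mean"), n_plaques=("n_plaques", "sum"))
        .sort_values(["animal", "section", "channel"], ignore_index=True)
    )
    per_animal = (
        per_section.groupby(["animal", "channel"], as_index=False)
        .agg(fraction=("fraction", "mean"), n_sections=("section", "nunique"))
        .sort_values(["animal", "channel"], ignore_index=True)
    )
    return (
        {"per_plaque": per_plaque, "per_section": per_section, "per_animal": per_animal},
        run,
    )


def run_diffuseness(
    config: QuantConfig, manifest_df: pd.DataFrame, base_dir=None
) -> tuple[dict[str, pd.DataFrame], RunManifest]:
    """Diffuseness analysis grouped by batch.

    ``manifest_df`` needs columns ``batch``, ``animal``, ``role``
    (``positive`` | ``control``) and ``image``.  Percentile thresholds are
    pooled within each batch; per-animal indices are means over that
    animal's images.
    """
    if manifest_df.empty:
        raise ValueError("empty cohort: manifest has no rows")
    base = Path(base_dir) if base_dir else Path(".")
    run = RunManifest(config=config.to_dict())
    t0 = time.perf_counter()
    image_rows = []
    for batch, group in manifest_df.groupby("batch", sort=True):
        controls = [
            read_image(base / r["image"], pixel_size_um=config.pixel_size_um)
            for _, r in group[group["role"] == "control"].iterrows()
        ]
        positives = group[group["role"] == "positive"]
        if controls == [] or positives.empty:
            raise ValueError(f"batch {batch!r}: needs >=1 control and >=1 positive image")
        stacks = []
        for _, r in positives.iterrows():
            run.add_input(base / r["image"])
            stacks.append(read_stack(base / r["image"], pixel_size_um=config.pixel_size_um))
        results, table = diffuseness_pipeline(
            stacks,
            controls,
            compact_percentile=config.compact_percentile,
            diffuse_percentile=config.diffuse_percentile,
            control_percentile=config.control_percentile,
            min_size_um2=config.min_size_x34_um2,
        )
        table = table.drop(columns=["image"])
        table.insert(0, "image", positives["image"].values)
        table.insert(0, "animal", positives["animal"].values)
        table.insert(0, "batch", batch)
        image_rows.append(table)
    _timed(run, "diffuseness", t0)
    per_image = pd.concat(image_rows, ignore_index=True)
    per_animal = (
        per_image.groupby(["batch", "animal"], as_index=False)
        .agg(diffuseness_index=("diffuseness_index", "mean"), n_images=("image", "count"))
        .sort_values(["batch", "animal"], ignore_index=True)
    )
    return {"per_image": per_image, "per_animal": per_animal}, run


def run_coloc(
    config: QuantConfig, manifest_df: pd.DataFrame, base_dir=None
) -> tuple[dict[str, pd.DataFrame], RunManifest]:
    """Mander's colocalization over aligned stack pairs.

    ``manifest_df`` needs columns ``animal``, ``field``, ``image_a``,
    ``image_b``, ``channel_a``, ``channel_b``; thresholds come from
    ``config.coloc_thresholds`` keyed by channel name (default 0).
    """
    if manifest_df.empty:
        raise ValueError("empty cohort: manifest has no rows")
    base = Path(base_dir) if base_dir else Path(".")
    run = RunManifest(config=config.to_dict())
    t0 = time.perf_counter()
    rows = []
    for _, r in manifest_df.iterrows():
        run.add_input(base / r["image_a"])
        run.add_input(base / r["image_b"])
        a = read_stack(base / r["image_a"], pixel_size_um=config.pixel_size_um)
        b = read_stack(base / r["image_b"], pixel_size_um=config.pixel_size_um)
        res = manders(
            a,
            b,
            config.coloc_thresholds.get(r["channel_a"], 0.0),
            config.coloc_thresholds.get(r["channel_b"], 0.0),
        )
        rows.append(
            {
                "animal": r["animal"],
                "field": r["field"],
                "channel_a": r["channel_a"],
                "channel_b": r["channel_b"],
                "m1": np.nan if res.m1 is None else res.m1,
                "m2": np.nan if res.m2 is None else res.m2,
                "threshold_a": res.threshold_a,
                "threshold_b": res.threshold_b,
            }
        )
    _timed(run, "coloc", t0)
    per_field = pd.DataFrame(rows)
    per_animal = (
        per_field.groupby(["animal", "channel_a", "channel_b"], as_index=False)
        .agg(m1=("m1", "mean"), m2=("m2", "mean"), n_fields=("field", "count"))
        .sort_values(["animal", "channel_a", "channel_b"], ignore_index=True)
    )
    return {"per_field": per_field, "per_animal": per_animal}, run


def run_modules(
    config: QuantConfig, expression_path, groups_path, gmt_path
) -> tuple[dict[str, pd.DataFrame], RunManifest]:
    """Gene-module scoring and Welch comparisons from files."""
    run = RunManifest(config=config.to_dict())
    for p in (expression_path, groups_path, gmt_path):
        run.add_input(p)
    t0 = time.perf_counter()
    matrix = read_expression(expression_path)
    groups = read_groups(groups_path)
    gene_sets = read_gmt(gmt_path)
    matrix = matrix[sorted(matrix.columns)]
    scores = score_gene_sets(matrix, gene_sets, floor=config.log2_floor)
    comparisons = compare_gene_sets(scores, groups)
    _timed(run, "modules", t0)
    return {"scores": scores, "comparisons": comparisons}, run


def write_tables(tables: dict[str, pd.DataFrame], out_dir, prefix: str) -> list[Path]:
    """Write each table as ``<prefix>_<name>.csv`` with stable formatting."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, tab in tables.items():
        p = out / f"{prefix}_{name}.csv"
        tab.to_csv(p, index=False, float_format="%.9g")
        paths.append(p)
    return paths
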