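"""Batch orchestration of the full pipeline.

One image runs preprocess -> Hough detection -> post-processing ->
quantification; a batch walks a ``group/dayN/*.png|tif|jpg`` tree,
writes one report per image, and assembles the long-format timecourse
table for external group statistics.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import PipelineConfig
from .hough import LineSegment, detect_lines
from .overlay import render_overlay
from .postprocess import PolylineCell, merge_fragments, remove_duplicates
from .preprocess import preprocess_image
from .quantify import MorphologyReport, assemble_timecourse, summarize

logger = logging.getLogger("cellhough")

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
MIN_IMAGE_SIDE = 32


def process_array(
    img: np.ndarray,
    config: PipelineConfig | None = None,
    image_id: str = "image",
    group: str | None = None,
    day: int | None = None,
) -> tuple[MorphologyReport, list[PolylineCell], np.ndarray]:
    """Run the full pipeline on an in-memory image.

    Returns the report, the merged per-cell polylines, and the binary
    edge map (useful for overlays and debugging).  Deterministic:
    identical input and config give identical output.
    """
    config = config or PipelineConfig()
    if min(img.shape[:2]) < MIN_IMAGE_SIDE:
        raise ValueError(
            f"image {image_id!r} is smaller than "
            f"{MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE} pixels"
        )
    edges = preprocess_image(
        img,
        normalize=config.normalize,
        median_kernel=config.median_kernel,
        canny_sigma=config.canny_sigma,
        canny_low=config.canny_low,
        canny_high=config.canny_high,
    )
    segments = detect_lines(
        edges,
        theta_step=config.theta_step,
        rho_step=config.rho_step,
        min_votes=config.min_votes,
        nhood=config.nhood,
        min_length=config.min_length,
        max_gap=config.max_gap,
        lateral_tol=config.lateral_tol,
    )
    segments = remove_duplicates(segments, dist_thresh=config.dup_dist,
                                 angle_thresh=config.dup_angle)
    cells = merge_fragments(segments, join_tol=config.join_tol)
    report = summarize(cells, image_id=image_id, group=group, day=day)
    return report, cells, edges


def run_image(
    path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    *,
    group: str | None = None,
    day: int | None = None,
    overlay: bool = False,
    debug_dump: bool = False,
) -> MorphologyReport:
    """Process one image file; optionally write report, tables, overlay.

    Outputs under ``out_dir`` (when given): ``<stem>.report.json`` (the
    report plus the exact config used), ``<stem>.segments.csv``,
    ``<stem>.cells.csv``, and with ``overlay`` a ``<stem>.overlay.png``.
    ``debug_dump`` additionally writes the enhanced gray and edge
    images.
    """
    path = Path(path)
    config = config or PipelineConfig()
    try:
        img = iio.imread(path)
    except Exception as exc:  # imageio raises various types
        raise OSError(f"cannot read image {path}: {exc}") from exc
    report, cells, edges = process_array(
        img, config, image_id=path.stem, group=group, day=day
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = path.stem
        payload = report.to_dict()
        payload["config"] = config.to_dict()
        (out_dir / f"{stem}.report.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
        segments_table(cells, image_id=stem).to_csv(
            out_dir / f"{stem}.segments.csv", index=False
        )
        cells_table(cells, image_id=stem).to_csv(
            out_dir / f"{stem}.cells.csv", index=False
        )
        if overlay:
            iio.imwrite(out_dir / f"{stem}.overlay.png",
                        render_overlay(img, cells))
        if debug_dump:
            _, inter = preprocess_image(
                img, normalize=config.normalize,
                median_kernel=config.median_kernel,
                canny_sigma=config.canny_sigma,
                canny_low=config.canny_low,
                canny_high=config.canny_high,
                return_intermediates=True,
            )
            iio.imwrite(out_dir / f"{stem}.enhanced.png",
                        np.round(inter["enhanced"] * 255).astype(np.uint8))
            iio.imwrite(out_dir / f"{stem}.edges.png",
                        (edges * np.uint8(255)))
    return report


def segments_table(cells: list[PolylineCell], image_id: str) -> pd.DataFrame:
    """Per-segment export: one row per member segment, keyed by cell."""
    rows = []
    for cell in cells:
        for seg in cell.segments:
            rows.append({
                "image_id": image_id, "cell_id": cell.id,
                "x1": seg.start[0], "y1": seg.start[1],
                "x2": seg.end[0], "y2": seg.end[1],
                "theta_deg": np.degrees(seg.theta), "rho_px": seg.rho,
                "length_px": seg.length,
            })
    return pd.DataFrame(rows, columns=[
        "image_id", "cell_id", "x1", "y1", "x2", "y2",
        "theta_deg", "rho_px", "length_px",
    ])


def cells_table(cells: list[PolylineCell], image_id: str) -> pd.DataFrame:
    rows = [{"image_id": image_id, "cell_id": c.id,
             "n_segments": len(c.segments),
             "total_length_px": c.total_length} for c in cells]
    return pd.DataFrame(rows, columns=[
        "image_id", "cell_id", "n_segments", "total_length_px",
    ])


_DAY_RE = re.compile(r"day[ _-]?(\d+)$", re.IGNORECASE)


def run_batch(
    root: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    **image_kwargs,
) -> pd.DataFrame:
    """Process a ``group/dayN/*.png|tif|jpg`` tree into a tidy table.

    Per-image failures are logged and skipped (the failure count is
    logged at the end); an empty tree is an error.  Rerunning on an
    unchanged tree reproduces the table exactly.
    """
    root = Path(root)
    config = config or PipelineConfig()
    reports: list[MorphologyReport] = []
    n_failed = 0
    for group_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for day_dir in sorted(p for p in group_dir.iterdir() if p.is_dir()):
            m = _DAY_RE.search(day_dir.name)
            day = int(m.group(1)) if m else None
            for img_path in sorted(day_dir.iterdir()):
                if img_path.suffix.lower() not in IMAGE_SUFFIXES:
                    continue
                try:
                    reports.append(run_image(
                        img_path, config,
                        out_dir=out_dir, group=group_dir.name, day=day,
                        **image_kwargs,
                    ))
                except Exception as exc:
                    n_failed += 1
                    logger.warning("skipping %s: %s", img_path, exc)
    if not reports and not n_failed:
        raise FileNotFoundError(f"no images found under {root}")
    if n_failed:
        logger.warning("%d image(s) failed and were skipped", n_failed)
    table = assemble_timecourse(reports)
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "timecourse.csv", index=False)
    return table
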