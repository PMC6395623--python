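"""Batch execution over image directories and aggregate reporting.

Runs the directionality pipeline on every image under a directory, grouping
results into series by subdirectory (a series is typically one experimental
condition).  Per-file failures are collected and reported without aborting
the rest of the batch; per-series summaries give the mean and range of
eccentricity and angular standard deviation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .directionality import AlignmentResult, analyze_image
from .errors import FibralignError

log = logging.getLogger("fibralign")

IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}

RESULT_COLUMNS = ["source_id", "series", "crop_px", "corner_px", "cutoff",
                  "eccentricity", "mu_deg", "sigma_deg", "n_sectors", "flags"]


@dataclass
class BatchReport:
    """Outcome of a directory run: per-image rows, series summary, failures."""

    results: pd.DataFrame
    summary: pd.DataFrame
    errors: list[tuple[str, str]] = field(default_factory=list)  # (file, message)


def result_row(res: AlignmentResult, config: AnalysisConfig,
               series: str = "") -> dict:
    return {
        "source_id": res.source_id,
        "series": series,
        "crop_px": config.crop_px,
        "corner_px": config.corner_px,
        "cutoff": res.cutoff,
        "eccentricity": res.eccentricity_eps,
        "mu_deg": res.mu_deg,
        "sigma_deg": res.sigma_deg,
        "n_sectors": config.n_sectors,
        "flags": ";".join(res.flags),
    }


def result_json(res: AlignmentResult, config: AnalysisConfig) -> str:
    """One JSON record per image, mirroring the CSV columns."""
    row = result_row(res, config)
    return json.dumps(row, sort_keys=True, indent=2)


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def list_images(image_dir: Path) -> list[Path]:
    return sorted(p for p in Path(image_dir).rglob("*")
                  if p.suffix.lower() in IMAGE_SUFFIXES and p.is_file())


def run_batch(image_dir, config: AnalysisConfig | None = None) -> BatchReport:
    """Analyse every readable image under ``image_dir``.

    Series membership is the image's subdirectory path relative to
    ``image_dir`` ("." for top-level files).  Raises
    :class:`~fibralign.errors.FibralignError` if the directory holds no
    images at all; individual failures are logged and returned in
    ``BatchReport.errors`` instead of aborting.
    """
    cfg = config if config is not None else AnalysisConfig()
    image_dir = Path(image_dir)
    files = list_images(image_dir)
    if not files:
        raise FibralignError(f"no images (*.tif, *.tiff, *.png) under {image_dir}")
    log.info("fibralign %s analysing %d images with %s",
             __version__, len(files), cfg.to_dict())
    rows, errors = [], []
    for path in files:
        series = str(path.parent.relative_to(image_dir))
        try:
            res = analyze_image(path, cfg)
        except Exception as exc:
            log.warning("failed on %s: %s", path, exc)
            errors.append((str(path.relative_to(image_dir)), str(exc)))
            continue
        log.info("%s sha256=%s eps=%.4f mu=%.2f sigma=%.2f",
                 path.name, _file_sha256(path)[:12], res.eccentricity_eps,
                 res.mu_deg, res.sigma_deg)
        rows.append(result_row(res, cfg, series=series))
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    summary = summarize_series(results)
    return BatchReport(results=results, summary=summary, errors=errors)


def summarize_series(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and range of eccentricity and sigma per series."""
    if results.empty:
        return pd.DataFrame(columns=["series", "n_images",
                                     "eccentricity_mean", "eccentricity_min",
                                     "eccentricity_max", "sigma_mean",
                                     "sigma_min", "sigma_max"])
    g = results.groupby("series", sort=True)
    summary = pd.DataFrame({
        "n_images": g.size(),
        "eccentricity_mean": g["eccentricity"].mean(),
        "eccentricity_min": g["eccentricity"].min(),
        "eccentricity_max": g["eccentricity"].max(),
        "sigma_mean": g["sigma_deg"].mean(),
        "sigma_min": g["sigma_deg"].min(),
        "sigma_max": g["sigma_deg"].max(),
    }).reset_index()
    return summary


def markdown_report(report: BatchReport) -> str:
    """Human-readable per-series summary of the equivalent-ellipse statistics."""
    lines = ["# Directionality summary", ""]
    lines.append("| series | n | eccentricity (mean [min, max]) | "
                 "sigma deg (mean [min, max]) |")
    lines.append("|---|---|---|---|")
    for _, r in report.summary.iterrows():
        lines.append(
            f"| {r['series']} | {int(r['n_images'])} "
            f"| {r['eccentricity_mean']:.3f} "
            f"[{r['eccentricity_min']:.3f}, {r['eccentricity_max']:.3f}] "
            f"| {r['sigma_mean']:.1f} "
            f"[{r['sigma_min']:.1f}, {r['sigma_max']:.1f}] |")
    if report.errors:
        lines += ["", "## Errors", ""]
        for name, msg in report.errors:
            lines.append(f"- `{name}`: {msg}")
    return "\n".join(lines) + "\n"
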