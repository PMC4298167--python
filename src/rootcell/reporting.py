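"""Tabulated output, review overlays and ROI export.

The measurement table is a tab-separated file whose header uses the
tool's standard abbreviations (ROOTA, ELA, CTXA, STELEA, CMA, NCM, NM,
NCL, NCF1..NCFk).  Overlays re-draw the selections and counting markers
on the grayscale image for after-the-fact review; ROI files are portable
JSON documents holding every contour, area and counting line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import imageio.v3 as iio

from .pipeline import MeasurementRecord, PipelineArtifacts

CONTOUR_COLOR = (255, 255, 0)      # yellow: region edges
LAYER_MARKER_COLOR = (255, 0, 255)  # magenta: cell-layer maxima
CELL_MARKER_COLOR = (0, 255, 0)     # green: cell-file maxima


def _fmt_area(v: float, unit: str) -> str:
    return f"{v:.0f}" if unit == "px" else f"{v:.2f}"


def format_record(rec: MeasurementRecord, n_files: int) -> list:
    row = [rec.image_id, rec.unit,
           _fmt_area(rec.roota, rec.unit), _fmt_area(rec.ela, rec.unit),
           _fmt_area(rec.ctxa, rec.unit), _fmt_area(rec.stelea, rec.unit),
           _fmt_area(rec.cma, rec.unit), str(rec.ncm),
           "NA" if rec.nm is None else str(rec.nm), f"{rec.ncl:.2f}"]
    ncf = list(rec.ncf) + [None] * (n_files - len(rec.ncf))
    row += ["NA" if v is None else str(v) for v in ncf[:n_files]]
    return row


def write_table(records, path) -> None:
    """Write the measurement table as a TSV file (byte-deterministic)."""
    records = list(records)
    if records:
        units = {r.unit for r in records}
        if len(units) > 1:
            raise ValueError(f"records mix unit modes: {sorted(units)}")
    n_files = max((len(r.ncf) for r in records), default=0)
    header = ["image_id", "unit", "ROOTA", "ELA", "CTXA", "STELEA", "CMA",
              "NCM", "NM", "NCL"] + [f"NCF{i + 1}" for i in range(n_files)]
    lines = ["\t".join(header)]
    for rec in records:
        lines.append("\t".join(format_record(rec, n_files)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_table(path):
    """Read a measurement TSV back as a list of dicts (strings kept as written)."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]


def _draw_points(canvas, pts, color, size=1):
    h, w = canvas.shape[:2]
    for (r, c) in pts:
        r, c = int(round(r)), int(round(c))
        r0, r1 = max(0, r - size), min(h, r + size + 1)
        c0, c1 = max(0, c - size), min(w, c + size + 1)
        canvas[r0:r1, c0:c1] = color


def export_overlay(img, artifacts: PipelineArtifacts, path) -> None:
    """Save the image with selections and counting markers superimposed."""
    px = img.pixels if hasattr(img, "pixels") else np.asarray(img)
    canvas = np.stack([px] * 3, axis=-1).astype(np.uint8)
    for sel in artifacts.selections.values():
        for contour in sel.contour:
            _draw_points(canvas, contour, CONTOUR_COLOR, size=0)
    cy, cx = artifacts.polar_center
    step = 2 * np.pi / artifacts.n_angles
    for prof in artifacts.layer_profiles:
        theta = prof.fixed_coord * step
        pts = [(cy - r * np.sin(theta), cx + r * np.cos(theta)) for r in prof.maxima]
        _draw_points(canvas, pts, LAYER_MARKER_COLOR)
    for prof in artifacts.file_profiles:
        r = prof.fixed_coord
        pts = [(cy - r * np.sin(a * step), cx + r * np.cos(a * step))
               for a in prof.maxima]
        _draw_points(canvas, pts, CELL_MARKER_COLOR)
    iio.imwrite(Path(path), canvas)


def _profile_to_dict(prof) -> dict:
    return {
        "orientation": prof.orientation,
        "fixed_coord": float(prof.fixed_coord),
        "span": [int(prof.span[0]), int(prof.span[1])],
        "maxima": [int(m) for m in prof.maxima],
        "raw_count": int(prof.raw_count),
        "coverage": float(prof.coverage),
        "extrapolated_count": int(prof.extrapolated_count),
        "noise_tolerance": float(prof.noise_tolerance),
    }


def export_rois(artifacts: PipelineArtifacts, path) -> dict:
    """Write every selection and counting line as a JSON ROI document."""
    doc = {
        "image_id": artifacts.record.image_id,
        "unit": artifacts.record.unit,
        "selections": [],
        "profiles": [],
        "measurements": {k: v for k, v in artifacts.record.to_dict().items()
                         if k not in ("image_id", "unit")},
    }
    for name, sel in artifacts.selections.items():
        doc["selections"].append({
            "label": sel.label,
            "area_px": int(sel.area_px),
            "area_units": None if sel.area_units is None else float(sel.area_units),
            "n_components": int(sel.n_components),
            "contours": [np.asarray(c).tolist() for c in sel.contour],
        })
    for prof in list(artifacts.layer_profiles) + list(artifacts.file_profiles):
        doc["profiles"].append(_profile_to_dict(prof))
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
    return doc


def load_rois(path) -> dict:
    """Load an ROI document written by :func:`export_rois`."""
    return json.loads(Path(path).read_text())
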