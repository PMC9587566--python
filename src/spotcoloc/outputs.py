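"""Result serialization: the CSV statistics table and the visual report.

The CSV lists one row per analyzed image/series with particle and cell
counts, the per-cell co-localization statistic and the parameters used
(audit trail).  The report renders each channel with a red circular overlay
at every detected particle, plus a merged page marking the matched pairs,
for visual inspection of the detection quality.  Overlay coordinates are
taken verbatim from the particle tables — nothing is re-detected at render
time.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
from matplotlib.backends.backend_pdf import PdfPages  # noqa: E402
from matplotlib.patches import Circle  # noqa: E402

from .cell_stats import AnalysisRecord  # noqa: E402
from .colocalization import MatchSet  # noqa: E402
from .detection import ParticleTable  # noqa: E402
from .projection import Projection2D  # noqa: E402

#: Column order of the results CSV.
CSV_SCHEMA = ("image_id", "series", "n_cells", "n_particles_a", "n_particles_b",
              "n_coloc", "coloc_per_cell", "percentile", "sigma", "diameter",
              "max_displacement")

_PARAM_COLUMNS = ("percentile", "sigma", "diameter", "max_displacement")


def records_to_dataframe(records: list[AnalysisRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "image_id": rec.image_id,
            "series": rec.series,
            "n_cells": rec.n_cells,
            "n_particles_a": rec.n_particles_a,
            "n_particles_b": rec.n_particles_b,
            "n_coloc": rec.n_coloc,
            "coloc_per_cell": rec.coloc_per_cell,
        }
        for col in _PARAM_COLUMNS:
            row[col] = rec.parameters.get(col, "")
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CSV_SCHEMA))


def _fmt(value) -> str:
    if value is None or value == "":
        return ""
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        if float(value).is_integer() and abs(value) < 1e15:
            return str(int(value)) if isinstance(value, (int, np.integer)) \
                else f"{value:.3f}"
        return f"{value:.3f}"
    return str(value)


def write_csv(records: list[AnalysisRecord], path: str | Path) -> Path:
    """Write the results table as RFC-4180 CSV ('.' decimal separator).

    Counts are written as integers, fractional quantities with 3 decimals;
    a read-back reproduces every value, and write→read→write is
    byte-stable.
    """
    path = Path(path)
    df = records_to_dataframe(records)
    out = df.copy()
    for col in ("n_cells", "coloc_per_cell", "percentile", "sigma",
                "max_displacement"):
        out[col] = [_fmt(v) if not (isinstance(v, float) and np.isnan(v)) else ""
                    for v in df[col]]
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a results CSV back into a DataFrame with numeric columns parsed."""
    return pd.read_csv(path)


def render_report(images: dict[str, Projection2D],
                  tables: dict[str, ParticleTable],
                  matches: MatchSet | None,
                  path: str | Path,
                  diameter: float = 9.0,
                  title: str = "") -> dict:
    """Render the visual-inspection report (PDF, or PNG per page).

    One page per channel with a red circle of radius ``diameter / 2`` at
    every detected particle, then a merged page where matched pairs are
    marked.  Layout is deterministic for identical inputs.

    Returns a render log: ``{"pages": [{"title", "n_circles"}, ...],
    "n_pair_markers": int, "paths": [...]}`` — used by tests to verify that
    overlay counts equal table row counts without parsing the PDF.
    """
    path = Path(path)
    log: dict = {"pages": [], "n_pair_markers": 0, "paths": []}
    roles = sorted(images)
    figures: list[plt.Figure] = []

    for role in roles:
        fig, ax = plt.subplots(figsize=(6, 6))
        ax.imshow(np.asarray(images[role].plane, dtype=np.float64),
                  cmap="gray", interpolation="nearest")
        n_circles = 0
        table = tables.get(role)
        if table is not None:
            for _, row in table.data.iterrows():
                ax.add_patch(Circle((row["col"], row["row"]), radius=diameter / 2,
                                    edgecolor="red", facecolor="none", lw=0.8))
                n_circles += 1
        ax.set_title(f"{title} {role} — {n_circles} particles".strip())
        ax.set_axis_off()
        figures.append(fig)
        log["pages"].append({"title": role, "n_circles": n_circles})

    if matches is not None and len(roles) >= 2:
        fig, ax = plt.subplots(figsize=(6, 6))
        merged = _merge_rgb(images, roles)
        ax.imshow(merged, interpolation="nearest")
        coords = {r: {int(i): (row, col) for i, row, col in
                      zip(tables[r].ids, tables[r].coords[:, 0],
                          tables[r].coords[:, 1])}
                  for r in roles if r in tables}
        n_markers = 0
        for id_a, id_b, _dist in matches.pairs:
            ra, ca = coords[roles[0]][id_a]
            rb, cb = coords[roles[1]][id_b]
            ax.add_patch(Circle(((ca + cb) / 2, (ra + rb) / 2),
                                radius=diameter / 2 + 1,
                                edgecolor="yellow", facecolor="none", lw=1.0))
            n_markers += 1
        ax.set_title(f"{title} merged — {n_markers} co-localized".strip())
        ax.set_axis_off()
        figures.append(fig)
        log["pages"].append({"title": "merged", "n_circles": n_markers})
        log["n_pair_markers"] = n_markers

    if path.suffix.lower() == ".pdf":
        with PdfPages(path) as pdf:
            for fig in figures:
                pdf.savefig(fig)
        log["paths"].append(str(path))
    else:
        stem = path.with_suffix("")
        for i, fig in enumerate(figures):
            page_path = Path(f"{stem}_page{i}.png")
            fig.savefig(page_path, dpi=120)
            log["paths"].append(str(page_path))
    for fig in figures:
        plt.close(fig)
    return log


def _merge_rgb(images: dict[str, Projection2D], roles: list[str]) -> np.ndarray:
    shape = images[roles[0]].shape
    rgb = np.zeros(shape + (3,), dtype=np.float64)
    for channel_idx, role in enumerate(roles[:3]):
        plane = np.asarray(images[role].plane, dtype=np.float64)
        top = plane.max()
        rgb[..., channel_idx] = plane / top if top > 0 else 0.0
    return rgb
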