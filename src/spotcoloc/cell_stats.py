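"""Fractional cell counting and per-image summary statistics.

A field of view rarely contains only whole cells: nuclei clipped by the
image border would bias a naive count.  Instead of dropping them, each
border-touching nucleus contributes its visible area divided by the average
area of a fully contained nucleus, capped at 1.  The per-image summary then
reports co-localized objects per cell using this fractional total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .colocalization import MatchSet
from .detection import ParticleTable
from .segmentation import RoiMask


@dataclass(frozen=True)
class CellCountEstimate:
    """Cell count with border-clipped nuclei included as area fractions."""

    n_full: int
    fractional_sum: float
    avg_area: float
    per_label: tuple[tuple[int, float, bool, float], ...]
    """(label, area_px2, border_touching, contribution) per nucleus."""

    @property
    def total(self) -> float:
        return self.n_full + self.fractional_sum


def count_cells(nuclei_mask: RoiMask, border_margin: int = 1) -> CellCountEstimate:
    """Estimate the number of cells from a labeled nuclei mask.

    A label is border-touching iff any of its pixels lies within
    ``border_margin`` pixels of the image edge.  The average nucleus area is
    the mean over non-border labels (median over all labels when every
    nucleus touches the border, since truncated areas would bias the mean
    downward).  Border labels contribute ``min(area / avg_area, 1)``;
    interior labels contribute 1.  An empty mask gives total 0.
    """
    labels = nuclei_mask.labels
    label_ids = np.unique(labels[labels > 0])
    if label_ids.size == 0:
        return CellCountEstimate(n_full=0, fractional_sum=0.0, avg_area=0.0,
                                 per_label=())
    areas = {int(l): int(np.count_nonzero(labels == l)) for l in label_ids}
    ring = np.zeros(labels.shape, dtype=bool)
    m = border_margin
    ring[:m], ring[-m:], ring[:, :m], ring[:, -m:] = True, True, True, True
    border_ids = set(int(l) for l in np.unique(labels[ring]) if l > 0)
    interior_areas = [a for l, a in areas.items() if l not in border_ids]
    if interior_areas:
        avg_area = float(np.mean(interior_areas))
    else:
        avg_area = float(np.median(list(areas.values())))
    per_label = []
    n_full = 0
    fractional = 0.0
    for l in sorted(areas):
        touching = l in border_ids
        if touching:
            contribution = min(areas[l] / avg_area, 1.0) if avg_area > 0 else 0.0
            fractional += contribution
        else:
            contribution = 1.0
            n_full += 1
        per_label.append((l, float(areas[l]), touching, contribution))
    return CellCountEstimate(n_full=n_full, fractional_sum=fractional,
                             avg_area=avg_area, per_label=tuple(per_label))


@dataclass(frozen=True)
class AnalysisRecord:
    """Per-image quantitative summary feeding the results table."""

    image_id: str
    series: int
    n_cells: float
    n_particles_a: int
    n_particles_b: int
    n_coloc: int
    coloc_per_cell: float | None
    parameters: dict = field(default_factory=dict)


def summarize(matches: MatchSet, table_a: ParticleTable, table_b: ParticleTable,
              cells: CellCountEstimate, image_id: str = "", series: int = 0,
              parameters: dict | None = None) -> AnalysisRecord:
    """Assemble the per-image record; all inputs must come from one image.

    ``coloc_per_cell`` is defined only when the cell total is positive;
    otherwise it is flagged missing (``None``) and, if co-localized pairs
    exist anyway, a warning is emitted.
    """
    n_coloc = matches.n_coloc
    total = cells.total
    if total > 0:
        coloc_per_cell = n_coloc / total
    else:
        coloc_per_cell = None
        if n_coloc > 0:
            warnings.warn(
                f"{image_id or 'image'}: {n_coloc} co-localized particles but "
                "zero cells counted; coloc_per_cell flagged missing",
                stacklevel=2,
            )
    return AnalysisRecord(
        image_id=image_id, series=series, n_cells=float(total),
        n_particles_a=len(table_a), n_particles_b=len(table_b),
        n_coloc=n_coloc, coloc_per_cell=coloc_per_cell,
        parameters=dict(parameters or {}),
    )
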