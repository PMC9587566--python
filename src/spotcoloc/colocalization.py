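"""Cross-channel particle matching and the pixel-correlation comparator.

Two particles are co-localized when their centers lie within the maximum
displacement ``r_max`` (by default the particle diameter).  Because a naive
per-particle nearest-neighbour rule can pair one particle twice, matching is
posed as a one-to-one assignment: among all matchings whose pair distances
do not exceed ``r_max``, take one with the maximum number of pairs, and
among those the minimum total squared displacement.  The optimum is found
with the Hungarian algorithm on a big-M padded cost matrix; an independent
exhaustive enumerator certifies it on small instances.

A pixel-based Pearson correlation is provided for comparison with
intensity-correlation co-localization measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .detection import ParticleTable
from .segmentation import RoiMask


@dataclass(frozen=True)
class MatchSet:
    """One-to-one cross-channel particle pairs within ``r_max``.

    ``pairs`` holds ``(id_a, id_b, distance_px)`` sorted by ascending
    ``(id_a, id_b)``.
    """

    pairs: tuple[tuple[int, int, float], ...]
    r_max: float
    unmatched_a: tuple[int, ...] = field(default_factory=tuple)
    unmatched_b: tuple[int, ...] = field(default_factory=tuple)

    @property
    def n_coloc(self) -> int:
        return len(self.pairs)

    @property
    def total_sq_displacement(self) -> float:
        return float(sum(d * d for _, _, d in self.pairs))


def _coords_and_ids(table: ParticleTable) -> tuple[np.ndarray, np.ndarray]:
    return table.coords, table.ids


def match_particles(table_a: ParticleTable, table_b: ParticleTable,
                    r_max: float) -> MatchSet:
    """Optimally pair particles across channels within the displacement limit.

    Maximizes pair count subject to distance ≤ ``r_max``, then minimizes the
    total squared displacement.  Deterministic: pairs are reported in
    ascending ``(id_a, id_b)`` order.
    """
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    xa, ids_a = _coords_and_ids(table_a)
    xb, ids_b = _coords_and_ids(table_b)
    n, m = len(xa), len(xb)
    if n == 0 or m == 0:
        return MatchSet(pairs=(), r_max=r_max,
                        unmatched_a=tuple(ids_a), unmatched_b=tuple(ids_b))
    d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
    feasible = d2 <= r_max ** 2 + 1e-12
    # Big-M exceeds any total feasible cost, so the Hungarian optimum first
    # maximizes the number of feasible pairs, then minimizes sum of d^2.
    big_m = (r_max ** 2) * min(n, m) + 1.0
    cost = np.where(feasible, d2, big_m)
    rows, cols = linear_sum_assignment(cost)
    pairs = []
    matched_a, matched_b = set(), set()
    for i, j in zip(rows, cols):
        if feasible[i, j]:
            pairs.append((int(ids_a[i]), int(ids_b[j]), float(np.sqrt(d2[i, j]))))
            matched_a.add(int(ids_a[i]))
            matched_b.add(int(ids_b[j]))
    pairs.sort(key=lambda p: (p[0], p[1]))
    return MatchSet(
        pairs=tuple(pairs), r_max=r_max,
        unmatched_a=tuple(int(i) for i in ids_a if int(i) not in matched_a),
        unmatched_b=tuple(int(i) for i in ids_b if int(i) not in matched_b),
    )


_EXHAUSTIVE_GUARD = 12


def match_particles_exhaustive(table_a: ParticleTable, table_b: ParticleTable,
                               r_max: float) -> MatchSet:
    """Exact matching by enumeration over one-to-one assignments (test oracle).

    Same objective as :func:`match_particles`, computed by a memoized
    depth-first enumeration over which channel-b particle (or none) each
    channel-a particle takes.  Refuses instances larger than 12×12.
    """
    xa, ids_a = _coords_and_ids(table_a)
    xb, ids_b = _coords_and_ids(table_b)
    n, m = len(xa), len(xb)
    if n > _EXHAUSTIVE_GUARD or m > _EXHAUSTIVE_GUARD:
        raise ValueError(f"exhaustive matcher limited to {_EXHAUSTIVE_GUARD}x"
                         f"{_EXHAUSTIVE_GUARD} instances, got {n}x{m}")
    d2 = (((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
          if n and m else np.zeros((n, m)))
    r2 = r_max ** 2 + 1e-12

    @lru_cache(maxsize=None)
    def best(i: int, used: int) -> tuple[int, float, tuple]:
        """(−pairs, cost, assignment) optimum for particles i.. given used-b mask."""
        if i == n:
            return (0, 0.0, ())
        neg, cost, assign = best(i + 1, used)
        result = (neg, cost, ((i, None),) + assign)
        for j in range(m):
            if used & (1 << j) or d2[i, j] > r2:
                continue
            neg_j, cost_j, assign_j = best(i + 1, used | (1 << j))
            cand = (neg_j - 1, cost_j + d2[i, j], ((i, j),) + assign_j)
            if (cand[0], cand[1]) < (result[0], result[1]):
                result = cand
        return result

    _, _, assignment = best(0, 0)
    best.cache_clear()
    pairs = sorted(
        (int(ids_a[i]), int(ids_b[j]), float(np.sqrt(d2[i, j])))
        for i, j in assignment if j is not None
    )
    matched_a = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    return MatchSet(
        pairs=tuple(pairs), r_max=r_max,
        unmatched_a=tuple(int(i) for i in ids_a if int(i) not in matched_a),
        unmatched_b=tuple(int(i) for i in ids_b if int(i) not in matched_b),
    )


def pearson_pixel_correlation(image_a, image_b, mask: RoiMask | None = None) -> float:
    """Pearson correlation of pixel intensities inside the ROI.

    The pixel-based comparator to object-based co-localization: +1 for
    perfectly covarying channels, 0 for unrelated ones.  Requires ≥ 2
    in-mask pixels and non-constant intensities in both channels.
    """
    a = np.asarray(image_a.plane if hasattr(image_a, "plane") else image_a,
                   dtype=np.float64)
    b = np.asarray(image_b.plane if hasattr(image_b, "plane") else image_b,
                   dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mask is not None:
        if mask.shape != a.shape:
            raise ValueError(f"mask shape {mask.shape} != image shape {a.shape}")
        sel = mask.foreground
        a, b = a[sel], b[sel]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 in-mask pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("undefined correlation: a channel is constant in the ROI")
    return float(pearsonr(a, b)[0])
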