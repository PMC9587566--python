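"""Ground-truthed synthetic two-channel z-stack scenes.

The generator emulates the essentials of a confocal field of cultured
cells imaged for punctate co-localization: disk-like nuclei in the
counterstain channel, a dimmer cytoplasmic halo in both signal channels,
PSF-blurred point-like puncta spread over 2–3 adjacent focal planes, a
controllable fraction of spatially coincident (co-localized) spot pairs,
additive background, Poisson shot noise and Gaussian read noise.  Every
stage of the analysis pipeline can therefore be scored against exact truth
without any real microscopy data.

Two placement constraints keep the truth labels meaningful: spots of the
same channel are kept apart so the detector can resolve them, and
non-co-localized spots of opposite channels are kept further apart than the
matching radius — otherwise a chance-proximal pair would satisfy the
operational definition of co-localization while being labelled negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import ImageStack
from .segmentation import RoiMask


class PlacementError(RuntimeError):
    """Raised when spots cannot be placed under the separation constraints."""


@dataclass(frozen=True)
class SceneParams:
    """Synthetic scene configuration.

    Defaults model a desk-scale version of a confocal P-body field: a
    256×256 px frame, 8 focal planes, ~6 cells with 4 puncta per channel
    each, half of them co-localized with ≤1 px registration jitter.
    Intensities are per focal plane in 8-bit units; the effective peak
    signal-to-background ratio is ``spot_peak / (cyto_level + background)``.
    """

    image_size: tuple[int, int] = (256, 256)
    n_z: int = 8
    n_cells: int = 6
    nucleus_radius: tuple[float, float] = (10.0, 14.0)
    cyto_halo: float = 12.0
    spots_per_cell: int = 4
    coloc_fraction: float = 0.5
    coloc_jitter: float = 1.0
    spot_sigma: float = 1.5
    spot_peak: float = 150.0
    cyto_level: float = 20.0
    nucleus_level: float = 110.0
    background: float = 5.0
    poisson_noise: bool = True
    read_noise_sd: float = 2.0
    same_channel_min_distance: float = 13.0
    cross_channel_min_distance: float = 10.5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.coloc_fraction <= 1:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.n_z < 1 or self.n_z > 30:
            raise ValueError("n_z must be in [1, 30]")
        if min(self.image_size) <= 0 or self.n_cells < 0 or self.spots_per_cell < 0:
            raise ValueError("sizes must be positive")


@dataclass(frozen=True)
class SceneTruth:
    """Exact ground truth of a generated scene."""

    nuclei: tuple[tuple[float, float, float], ...]
    """(row, col, radius) per nucleus."""
    cell_radii: tuple[float, ...]
    spots_a: np.ndarray
    spots_b: np.ndarray
    pairs: tuple[tuple[int, int], ...]
    """(index into spots_a, index into spots_b) for true co-localized pairs."""
    seed: int
    image_size: tuple[int, int] = (256, 256)

    @property
    def n_true_pairs(self) -> int:
        return len(self.pairs)

    def nuclei_label_mask(self) -> RoiMask:
        """Analytic labeled nuclei mask (1..K), for cell-count checks."""
        rows, cols = self.image_size
        rr, cc = np.mgrid[0:rows, 0:cols]
        labels = np.zeros((rows, cols), dtype=np.int32)
        for k, (r0, c0, rad) in enumerate(self.nuclei, start=1):
            labels[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2] = k
        return RoiMask(labels=labels, mode="nuclei", n_objects=len(self.nuclei))


def _place_cells(params: SceneParams, rng: np.random.Generator):
    rows, cols = params.image_size
    centers, radii_n, radii_c = [], [], []
    for _ in range(params.n_cells):
        for _attempt in range(5000):
            rad_n = rng.uniform(*params.nucleus_radius)
            rad_c = rad_n + params.cyto_halo
            r = rng.uniform(rad_c + 2, rows - rad_c - 2)
            c = rng.uniform(rad_c + 2, cols - rad_c - 2)
            if all((r - r2) ** 2 + (c - c2) ** 2 >= (rad_c + rc2 + 3) ** 2
                   for (r2, c2), rc2 in zip(centers, radii_c)):
                centers.append((r, c))
                radii_n.append(rad_n)
                radii_c.append(rad_c)
                break
        else:
            raise PlacementError(
                f"could not place {params.n_cells} non-overlapping cells in "
                f"{params.image_size}"
            )
    return centers, radii_n, radii_c


def _sample_cyto_point(center, rad_n, rad_c, rng):
    # Anywhere in the cell body: in a 2D projection, cytoplasmic puncta
    # from planes above/below the nucleus appear over the nuclear area too.
    r0, c0 = center
    radius = np.sqrt(rng.uniform(0.0, (rad_c - 2.5) ** 2))
    theta = rng.uniform(0, 2 * np.pi)
    return (r0 + radius * np.sin(theta), c0 + radius * np.cos(theta))


def _min_dist2(point, others) -> float:
    if len(others) == 0:
        return np.inf
    arr = np.asarray(others, dtype=np.float64)
    return float(((arr - np.asarray(point)) ** 2).sum(axis=1).min())


def generate_scene(params: SceneParams) -> tuple[ImageStack, SceneTruth]:
    """Render a 3-channel synthetic z-stack and return it with its truth.

    The number of true co-localized pairs is
    ``round(coloc_fraction * min(|spots_a|, |spots_b|))``; paired spots
    share coordinates up to independent per-axis jitter of at most
    ``coloc_jitter`` pixels.  The same seed always produces bit-identical
    voxels and truth.
    """
    rng = np.random.default_rng(params.seed)
    rows, cols = params.image_size
    centers, radii_n, radii_c = _place_cells(params, rng)

    n_spots = params.n_cells * params.spots_per_cell
    # Pairs are spread as evenly as possible over cells so every cell keeps
    # exactly spots_per_cell spots in both channels.
    n_pairs = int(round(params.coloc_fraction * n_spots))
    pairs_per_cell = [0] * params.n_cells
    if n_pairs and params.n_cells:
        base, rem = divmod(n_pairs, params.n_cells)
        extra = set(rng.choice(params.n_cells, size=rem, replace=False).tolist()) \
            if rem else set()
        pairs_per_cell = [base + (1 if ci in extra else 0)
                          for ci in range(params.n_cells)]

    spots_a: list[tuple[float, float]] = []
    spots_b: list[tuple[float, float]] = []
    free_a: list[tuple[float, float]] = []
    pairs: list[tuple[int, int]] = []
    for ci, (center, rn, rc) in enumerate(zip(centers, radii_n, radii_c)):
        placed = _place_cell_spots(params, rng, center, rn, rc,
                                   pairs_per_cell[ci], spots_a, spots_b, free_a)
        cell_a, cell_b_paired, cell_b_free = placed
        a_offset = len(spots_a)
        spots_a.extend(cell_a)
        k = pairs_per_cell[ci]
        free_a.extend(cell_a[k:])
        for local_ia, b_coord in enumerate(cell_b_paired):
            pairs.append((a_offset + local_ia, len(spots_b)))
            spots_b.append(b_coord)
        spots_b.extend(cell_b_free)

    spots_a_arr = np.asarray(spots_a, dtype=np.float64).reshape(-1, 2)
    spots_b_arr = np.asarray(spots_b, dtype=np.float64).reshape(-1, 2)

    voxels = _render(params, rng, centers, radii_n, radii_c,
                     spots_a_arr, spots_b_arr)
    stack = ImageStack(voxels=voxels, source="synthetic", series=0)
    truth = SceneTruth(
        nuclei=tuple((r, c, rad) for (r, c), rad in zip(centers, radii_n)),
        cell_radii=tuple(radii_c),
        spots_a=spots_a_arr, spots_b=spots_b_arr,
        pairs=tuple(pairs), seed=params.seed, image_size=params.image_size,
    )
    return stack, truth


def _place_cell_spots(params, rng, center, rad_n, rad_c, n_paired,
                      global_a, global_b, global_free_a):
    """Place one cell's spots in both channels, with cell-level backtracking.

    The first ``n_paired`` channel-a spots get a jittered channel-b twin;
    the remaining channel-b spots are free and must keep the cross-channel
    minimum distance from every non-paired channel-a spot.  Dead-ends are
    resolved by re-placing the whole cell.
    """
    same2 = params.same_channel_min_distance ** 2
    cross2 = params.cross_channel_min_distance ** 2
    n = params.spots_per_cell
    for _cell_attempt in range(80):
        rng_try = rng  # one stream; failed attempts advance it
        cell_a: list[tuple[float, float]] = []
        ok = True
        for _ in range(n):
            for _attempt in range(300):
                p = _sample_cyto_point(center, rad_n, rad_c, rng_try)
                if _min_dist2(p, global_a) >= same2 and \
                        _min_dist2(p, cell_a) >= same2:
                    cell_a.append(p)
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        cell_b_paired: list[tuple[float, float]] = []
        for ra, ca in cell_a[:n_paired]:
            jitter = (rng_try.uniform(-params.coloc_jitter,
                                      params.coloc_jitter, size=2)
                      if params.coloc_jitter > 0 else np.zeros(2))
            cell_b_paired.append((ra + jitter[0], ca + jitter[1]))
        free_a_here = cell_a[n_paired:]
        cell_b_free: list[tuple[float, float]] = []
        for _ in range(n - n_paired):
            for _attempt in range(300):
                p = _sample_cyto_point(center, rad_n, rad_c, rng_try)
                if (_min_dist2(p, global_b) >= same2
                        and _min_dist2(p, cell_b_paired + cell_b_free) >= same2
                        and _min_dist2(p, global_free_a) >= cross2
                        and _min_dist2(p, free_a_here) >= cross2
                        and _min_dist2(p, cell_a[:n_paired]) >= cross2
                        and _min_dist2(p, global_a) >= cross2):
                    cell_b_free.append(p)
                    break
            else:
                ok = False
                break
        if ok:
            return cell_a, cell_b_paired, cell_b_free
    raise PlacementError(
        f"could not place {n} spots per channel in a cell of radius "
        f"{rad_c:.1f} under the separation constraints")


def _soft_disk(shape, center, radius, rr, cc) -> np.ndarray:
    """Anti-aliased disk indicator with a ~1 px soft edge."""
    dist = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    return np.clip(radius + 0.5 - dist, 0.0, 1.0)


def _render(params, rng, centers, radii_n, radii_c, spots_a, spots_b):
    rows, cols = params.image_size
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)

    cyto = np.zeros((rows, cols))
    nuc = np.zeros((rows, cols))
    for center, rn, rc in zip(centers, radii_n, radii_c):
        cyto = np.maximum(cyto, _soft_disk((rows, cols), center, rc, rr, cc))
        nuc = np.maximum(nuc, _soft_disk((rows, cols), center, rn, rr, cc))

    # Spot z profile: full peak at the centre plane, half at its neighbours.
    z_centers_a = rng.integers(1, max(2, params.n_z - 1), size=len(spots_a))
    z_centers_b = rng.integers(1, max(2, params.n_z - 1), size=len(spots_b))

    def spot_plane(coords, z_centers, z):
        plane = np.zeros((rows, cols))
        sig2 = 2.0 * params.spot_sigma ** 2
        for (r0, c0), zc in zip(coords, z_centers):
            dz = abs(int(z) - int(zc))
            if dz > 1:
                continue
            weight = 1.0 if dz == 0 else 0.5
            rmin = max(0, int(r0) - 8); rmax = min(rows, int(r0) + 9)
            cmin = max(0, int(c0) - 8); cmax = min(cols, int(c0) + 9)
            sub_rr = rr[rmin:rmax, cmin:cmax]
            sub_cc = cc[rmin:rmax, cmin:cmax]
            plane[rmin:rmax, cmin:cmax] += (
                params.spot_peak * weight
                * np.exp(-((sub_rr - r0) ** 2 + (sub_cc - c0) ** 2) / sig2)
            )
        return plane

    voxels = np.zeros((params.n_z, 3, rows, cols), dtype=np.uint8)
    for z in range(params.n_z):
        chan_a = (params.background + params.cyto_level * cyto
                  + spot_plane(spots_a, z_centers_a, z))
        chan_b = (params.background + params.cyto_level * cyto
                  + spot_plane(spots_b, z_centers_b, z))
        chan_n = params.background + params.nucleus_level * nuc
        for idx, chan in enumerate((chan_a, chan_b, chan_n)):
            noisy = rng.poisson(np.clip(chan, 0, None)).astype(np.float64) \
                if params.poisson_noise else chan.copy()
            if params.read_noise_sd > 0:
                noisy = noisy + rng.normal(0.0, params.read_noise_sd,
                                           size=noisy.shape)
            voxels[z, idx] = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    return voxels


@dataclass(frozen=True)
class DetectionScore:
    """Detection quality against truth."""

    recall: float
    precision: float | None
    rmse: float | None
    n_matched: int


def score_against_truth(detected, truth_coords, tol: float) -> DetectionScore:
    """Score detections against true coordinates by optimal assignment.

    ``detected`` may be a ParticleTable or an (n, 2) coordinate array;
    ``truth_coords`` likewise.  Pairing uses the same optimal-assignment
    matcher as the analysis with ``r_max = tol``.  Precision is ``None``
    (undefined) when there are no detections; RMSE is over matched pairs.
    """
    from .colocalization import match_particles
    from .detection import ParticleTable

    if tol <= 0:
        raise ValueError("tol must be positive")
    det = detected if isinstance(detected, ParticleTable) \
        else ParticleTable.from_coords(np.asarray(detected))
    tru = truth_coords if isinstance(truth_coords, ParticleTable) \
        else ParticleTable.from_coords(np.asarray(truth_coords))
    matches = match_particles(tru, det, r_max=tol)
    n_matched = matches.n_coloc
    recall = n_matched / len(tru) if len(tru) else 1.0
    precision = (n_matched / len(det)) if len(det) else None
    rmse = None
    if n_matched:
        rmse = float(np.sqrt(np.mean([d ** 2 for _, _, d in matches.pairs])))
    return DetectionScore(recall=recall, precision=precision, rmse=rmse,
                          n_matched=n_matched)
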