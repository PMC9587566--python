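"""Sub-pixel spot localization, percentile sweep and plateau estimation."""

import numpy as np
import pandas as pd
import pytest

from spotcoloc import (DetectionParams, estimate_plateau, locate_particles,
                       sweep_percentiles)
from spotcoloc.detection import ParticleTable

from conftest import gaussian_spot_image


class TestParams:
    @pytest.mark.parametrize("diameter", [2, 4, 8, 1])
    def test_even_or_small_diameter_rejected(self, diameter):
        with pytest.raises(ValueError):
            DetectionParams(diameter=diameter)

    def test_default_separation(self):
        assert DetectionParams(diameter=9).sep == 10


class TestLocate:
    def test_blank_image_empty_table(self):
        table = locate_particles(np.zeros((64, 64)), DetectionParams())
        assert len(table) == 0

    def test_single_spot_subpixel_accuracy(self):
        img = gaussian_spot_image(centers=((20.0, 30.0),))
        table = locate_particles(img, DetectionParams(diameter=9))
        assert len(table) == 1
        row, col = table.coords[0]
        assert abs(row - 20.0) <= 0.1 and abs(col - 30.0) <= 0.1

    @pytest.mark.parametrize("centers", [
        ((20.0, 30.0), (40.0, 30.0)),
        ((15.25, 18.75), (35.5, 44.25)),
    ])
    def test_multiple_spots_each_within_tenth_pixel(self, centers):
        img = gaussian_spot_image(centers=centers)
        table = locate_particles(img, DetectionParams(diameter=9))
        assert len(table) == len(centers)
        found = sorted(map(tuple, table.coords))
        for (fr, fc), (tr, tc) in zip(found, sorted(centers)):
            assert abs(fr - tr) <= 0.1 and abs(fc - tc) <= 0.1

    def test_translation_equivariance_integer_shift(self):
        img = gaussian_spot_image(shape=(96, 96), centers=((40.0, 40.0),))
        base = locate_particles(img, DetectionParams(diameter=9)).coords[0]
        for dr, dc in ((7, 0), (0, -11), (5, 9)):
            shifted = np.roll(np.roll(img, dr, axis=0), dc, axis=1)
            coords = locate_particles(shifted, DetectionParams(diameter=9)).coords[0]
            np.testing.assert_allclose(coords, base + (dr, dc), atol=1e-9)

    def test_minmass_monotone_filter(self):
        img = gaussian_spot_image(centers=((20.0, 20.0), (45.0, 45.0)),
                                  peak=150.0) \
            + gaussian_spot_image(centers=((20.0, 45.0),), peak=40.0)
        counts = [len(locate_particles(img, DetectionParams(diameter=9, minmass=m)))
                  for m in (0.0, 100.0, 400.0, 1e6)]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 3 and counts[-1] == 0

    def test_ids_unique_and_mass_descending(self):
        img = gaussian_spot_image(centers=((20.0, 20.0), (45.0, 45.0)),
                                  peak=150.0) \
            + gaussian_spot_image(centers=((20.0, 45.0),), peak=60.0)
        table = locate_particles(img, DetectionParams(diameter=9))
        ids = table.data["particle_id"].to_numpy()
        assert len(set(ids)) == len(ids)
        mass = table.data["mass"].to_numpy()
        assert (np.diff(mass) <= 0).all()

    def test_separation_enforced(self):
        table = locate_particles(
            gaussian_spot_image(centers=((20.0, 20.0), (40.0, 20.0))),
            DetectionParams(diameter=9))
        d = np.linalg.norm(table.coords[0] - table.coords[1])
        assert d >= DetectionParams(diameter=9).sep


class TestSweep:
    def _denoised_pair(self, standard_scene):
        from spotcoloc import (RunConfig, apply_mask, gaussian_smooth,
                               project_normalized_stacked, project_saturated,
                               segment_roi, wbns)
        stack, truth = standard_scene
        cfg = RunConfig()
        sat_a = project_saturated(stack, "signal_a")
        sat_n = project_saturated(stack, "nuclear")
        roi = segment_roi(sat_a, sat_n, "cyto", cfg.cell_diameter)
        out = {}
        for role in ("signal_a", "signal_b"):
            proj = apply_mask(project_normalized_stacked(stack, role), roi)
            out[role] = gaussian_smooth(wbns(proj, 3, 1), 1.0)
        return out, truth

    def test_single_point_grid_matches_pipeline(self, standard_scene):
        from spotcoloc import RunConfig
        denoised, _ = self._denoised_pair(standard_scene)
        cfg = RunConfig()
        params = DetectionParams(diameter=9, minmass=cfg.minmass)
        sweep = sweep_percentiles(denoised["signal_a"], denoised["signal_b"],
                                  params, r_max=9.0, grid=[90.0])
        assert len(sweep) == 1
        from spotcoloc import analyze_stack
        rec, _ = analyze_stack(standard_scene[0], cfg)
        assert sweep.iloc[0]["n_a"] == rec.n_particles_a
        assert sweep.iloc[0]["n_coloc"] == rec.n_coloc

    def test_counts_non_increasing_in_percentile(self, standard_scene):
        denoised, _ = self._denoised_pair(standard_scene)
        params = DetectionParams(diameter=9, minmass=80.0)
        sweep = sweep_percentiles(denoised["signal_a"], denoised["signal_b"],
                                  params, r_max=9.0)
        assert (np.diff(sweep["n_a"]) <= 0).all()
        assert (np.diff(sweep["n_b"]) <= 0).all()

    def test_coloc_plateau_on_synthetic_scene(self, standard_scene):
        denoised, truth = self._denoised_pair(standard_scene)
        params = DetectionParams(diameter=9, minmass=80.0)
        sweep = sweep_percentiles(denoised["signal_a"], denoised["signal_b"],
                                  params, r_max=9.0)
        estimate = estimate_plateau(sweep, tolerance=0.1)
        assert estimate.found
        run = sweep[(sweep["percentile"] >= estimate.percentile_range[0])
                    & (sweep["percentile"] <= estimate.percentile_range[1])]
        assert len(run) >= 3
        g = truth.n_true_pairs
        assert run["n_coloc"].max() - run["n_coloc"].min() <= 0.1 * g

    @pytest.mark.parametrize("grid", [[], [50.0, 40.0], [120.0]])
    def test_bad_grids_rejected(self, grid):
        img = np.ones((16, 16))
        with pytest.raises(ValueError):
            sweep_percentiles(img, img, DetectionParams(), 9.0, grid)


class TestPlateau:
    def _sweep(self, counts, pcts=None):
        pcts = pcts if pcts is not None else list(range(len(counts)))
        return pd.DataFrame({"percentile": pcts, "n_a": 0, "n_b": 0,
                             "n_coloc": counts})

    def test_constant_counts_full_range(self):
        estimate = estimate_plateau(self._sweep([20, 20, 20, 20]), 0.1)
        assert estimate.found and estimate.count == 20
        assert estimate.percentile_range == (0, 3)

    def test_documented_run_example(self):
        estimate = estimate_plateau(self._sweep([50, 22, 20, 21, 20, 8]), 0.1)
        assert estimate.found
        assert estimate.count == 20.5
        assert estimate.percentile_range == (1, 4)

    def test_exhaustive_run_enumeration_oracle(self):
        counts = np.array([50, 22, 20, 21, 20, 8], dtype=float)
        tol = 0.1
        best = None
        for i in range(len(counts)):
            for j in range(i + 1, len(counts)):
                run = counts[i:j + 1]
                if run.max() - run.min() <= tol * np.median(run):
                    length = j - i + 1
                    if best is None or length > best[0] or \
                            (length == best[0] and i > best[1]):
                        best = (length, i, j)
        estimate = estimate_plateau(self._sweep(list(counts)), tol)
        assert best is not None
        assert estimate.count == np.median(counts[best[1]:best[2] + 1])

    def test_steep_slope_no_plateau(self):
        estimate = estimate_plateau(self._sweep([100, 80, 60, 40, 20]), 0.1)
        assert not estimate.found
        assert estimate.count == 60  # full-range median fallback

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            estimate_plateau(self._sweep([1, 2]), 0.1)


def test_particle_table_coords_round_trip():
    coords = np.array([[1.5, 2.5], [3.0, 4.0]])
    table = ParticleTable.from_coords(coords, channel="signal_a")
    np.testing.assert_array_equal(table.coords, coords)
    assert len(ParticleTable.empty()) == 0
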