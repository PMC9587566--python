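"""Cross-channel matching, the exhaustive oracle, and pixel correlation."""

import numpy as np
import pytest

from spotcoloc import (match_particles, match_particles_exhaustive,
                       pearson_pixel_correlation)
from spotcoloc.detection import ParticleTable
from spotcoloc.segmentation import RoiMask


def _table(coords):
    return ParticleTable.from_coords(np.asarray(coords, dtype=float))


class TestMatch:
    def test_identical_sets_all_matched_at_zero_distance(self):
        a = _table([(5, 5), (10, 10)])
        matches = match_particles(a, _table([(5, 5), (10, 10)]), r_max=4)
        assert matches.n_coloc == 2
        assert all(d == 0 for _, _, d in matches.pairs)

    def test_distance_beyond_rmax_unmatched(self):
        matches = match_particles(_table([(0, 0)]), _table([(0, 5)]), r_max=4)
        assert matches.n_coloc == 0
        assert matches.unmatched_a == (0,) and matches.unmatched_b == (0,)

    def test_min_displacement_breaks_feasible_tie(self):
        matches = match_particles(_table([(0, 0), (0, 3)]), _table([(0, 2)]),
                                  r_max=3)
        assert matches.pairs == ((1, 0, 1.0),)

    def test_distance_exactly_rmax_is_colocalized(self):
        matches = match_particles(_table([(0, 0)]), _table([(0, 3)]), r_max=3)
        assert matches.n_coloc == 1

    def test_empty_tables(self):
        empty = ParticleTable.empty()
        assert match_particles(empty, _table([(1, 1)]), 5).n_coloc == 0
        assert match_particles(empty, empty, 5).n_coloc == 0

    def test_avoids_nearest_neighbour_double_counting(self):
        # both a-particles are nearest to the same b-particle; the optimal
        # one-to-one assignment still pairs both
        a = _table([(0, 0), (0, 2)])
        b = _table([(0, 1), (0, 6)])
        matches = match_particles(a, b, r_max=4)
        assert matches.n_coloc == 2


class TestOracle:
    def test_oracle_equivalence_randomized(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n, m = rng.integers(1, 9, size=2)
            a = _table(rng.uniform(0, 40, (n, 2)))
            b = _table(rng.uniform(0, 40, (m, 2)))
            r_max = rng.uniform(2, 10)
            fast = match_particles(a, b, r_max)
            exact = match_particles_exhaustive(a, b, r_max)
            assert fast.n_coloc == exact.n_coloc
            assert fast.total_sq_displacement == pytest.approx(
                exact.total_sq_displacement, abs=1e-9)

    def test_guard(self):
        big = _table(np.random.default_rng(0).uniform(0, 10, (13, 2)))
        with pytest.raises(ValueError):
            match_particles_exhaustive(big, big, 3)

    def test_empty_vs_nonempty(self):
        assert match_particles_exhaustive(
            ParticleTable.empty(), _table([(0, 0)]), 2).n_coloc == 0


class TestProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = _table(rng.uniform(0, 30, (6, 2)))
        b = _table(rng.uniform(0, 30, (7, 2)))
        assert match_particles(a, b, 5).n_coloc == match_particles(b, a, 5).n_coloc

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_rmax(self, seed):
        rng = np.random.default_rng(seed + 50)
        a = _table(rng.uniform(0, 30, (8, 2)))
        b = _table(rng.uniform(0, 30, (8, 2)))
        counts = [match_particles(a, b, r).n_coloc for r in (1, 2, 4, 8, 16)]
        assert counts == sorted(counts)

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        pts_a = rng.uniform(10, 30, (6, 2))
        pts_b = rng.uniform(10, 30, (6, 2))
        base = match_particles(_table(pts_a), _table(pts_b), 5)
        shifted = match_particles(_table(pts_a + 100), _table(pts_b + 100), 5)
        assert [(p[0], p[1]) for p in base.pairs] == \
            [(p[0], p[1]) for p in shifted.pairs]
        np.testing.assert_allclose([p[2] for p in base.pairs],
                                   [p[2] for p in shifted.pairs], atol=1e-9)

    def test_invalid_rmax(self):
        with pytest.raises(ValueError):
            match_particles(_table([(0, 0)]), _table([(0, 0)]), 0)


class TestPearson:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (16, 16))
        assert pearson_pixel_correlation(img, img) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (16, 16))
        assert pearson_pixel_correlation(img, 255 - img) == pytest.approx(-1.0)

    def test_hand_computed_values_in_mask(self):
        a = np.zeros((2, 4)); b = np.zeros((2, 4))
        a[0] = [1, 2, 3, 4]; b[0] = [2, 4, 6, 8]
        labels = np.zeros((2, 4), dtype=np.int32); labels[0] = 1
        mask = RoiMask(labels=labels, mode="cyto", n_objects=1)
        assert pearson_pixel_correlation(a, b, mask) == pytest.approx(1.0)
        b[0] = [1, 3, 2, 4]
        # closed form: cov=1.25, sd_a=sd_b=sqrt(1.25) -> r=0.8
        assert pearson_pixel_correlation(a, b, mask) == pytest.approx(0.8)

    def test_constant_channel_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_pixel_correlation(np.ones((4, 4)),
                                      np.random.default_rng(0).uniform(size=(4, 4)))
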