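"""Fractional cell counting and the per-image summary record."""

import numpy as np
import pytest

from spotcoloc import count_cells, match_particles, summarize
from spotcoloc.detection import ParticleTable
from spotcoloc.segmentation import RoiMask


def _mask_with(labels):
    labels = np.asarray(labels, dtype=np.int32)
    return RoiMask(labels=labels, mode="nuclei", n_objects=int(labels.max()))


def _square(labels, top, left, size, value):
    labels[top:top + size, left:left + size] = value


class TestCountCells:
    def test_interior_plus_half_border_nucleus(self):
        labels = np.zeros((60, 60))
        _square(labels, 5, 5, 10, 1)     # 100 px2, interior
        _square(labels, 5, 25, 10, 2)
        _square(labels, 25, 5, 10, 3)
        labels[0:5, 40:50] = 4           # 50 px2, touches the top border
        estimate = count_cells(_mask_with(labels))
        assert estimate.n_full == 3
        assert estimate.avg_area == 100.0
        assert estimate.total == pytest.approx(3.5, abs=1e-12)

    def test_empty_mask_total_zero(self):
        estimate = count_cells(_mask_with(np.zeros((20, 20))))
        assert estimate.total == 0 and estimate.n_full == 0

    def test_oversized_border_nucleus_capped_at_one(self):
        labels = np.zeros((60, 60))
        _square(labels, 20, 20, 10, 1)   # interior 100 px2
        labels[0:12, 0:15] = 2           # border 180 px2 > avg
        estimate = count_cells(_mask_with(labels))
        assert estimate.total == pytest.approx(2.0)
        border = [p for p in estimate.per_label if p[2]]
        assert border[0][3] == 1.0

    def test_all_border_falls_back_to_median_area(self):
        labels = np.zeros((30, 30))
        labels[0:10, 2:12] = 1           # 100 px2 on border
        labels[0:5, 20:28] = 2           # 40 px2 on border
        estimate = count_cells(_mask_with(labels))
        assert estimate.avg_area == 70.0  # median of {100, 40}
        # 100 px2 capped at 1, plus 40/70 for the smaller fragment
        assert estimate.total == pytest.approx(1 + 40 / 70)

    def test_interior_only_mask_recovers_integer_count(self):
        labels = np.zeros((80, 80))
        for k, (r, c) in enumerate([(10, 10), (10, 40), (40, 10), (40, 40)], 1):
            _square(labels, r, c, 8, k)
        assert count_cells(_mask_with(labels)).total == 4.0

    def test_total_invariant_under_label_permutation(self):
        labels = np.zeros((40, 40))
        _square(labels, 10, 10, 8, 1)
        _square(labels, 25, 25, 6, 2)
        labels[0:4, 30:36] = 3
        base = count_cells(_mask_with(labels)).total
        permuted = np.zeros_like(labels)
        permuted[labels == 1] = 3
        permuted[labels == 2] = 1
        permuted[labels == 3] = 2
        assert count_cells(_mask_with(permuted)).total == pytest.approx(base)

    def test_clipping_reduces_total_by_area_fraction(self):
        # disk nucleus split by cropping: total drops by ~(A - a)/avg_area
        rr, cc = np.mgrid[0:80, 0:80]
        labels = np.zeros((80, 80))
        labels[(rr - 30) ** 2 + (cc - 30) ** 2 <= 100] = 1   # interior disk
        labels[(rr - 70) ** 2 + (cc - 70) ** 2 <= 100] = 2   # to be clipped
        full_area = np.count_nonzero(labels == 2)
        cropped = labels[:76, :76]
        visible = np.count_nonzero(cropped == 2)
        estimate = count_cells(_mask_with(cropped))
        expected = 1 + visible / np.count_nonzero(cropped == 1)
        assert estimate.total == pytest.approx(expected, abs=1e-12)
        assert estimate.total < 2.0 and visible < full_area


class TestSummarize:
    def _inputs(self, coords_a, coords_b, r_max=4.0):
        a = ParticleTable.from_coords(coords_a)
        b = ParticleTable.from_coords(coords_b)
        return match_particles(a, b, r_max), a, b

    def test_coloc_per_cell_division(self):
        labels = np.zeros((40, 40))
        _square(labels, 10, 10, 10, 1)
        cells = count_cells(_mask_with(labels))
        coords = [(i * 5.0 + 12, 20.0) for i in range(3)]
        matches, a, b = self._inputs(coords, coords)
        record = summarize(matches, a, b, cells, image_id="img")
        assert record.n_coloc == 3
        assert record.coloc_per_cell == pytest.approx(3.0)

    def test_zero_cells_flags_missing_and_warns(self):
        cells = count_cells(_mask_with(np.zeros((10, 10))))
        matches, a, b = self._inputs([(1.0, 1.0)], [(1.5, 1.0)])
        with pytest.warns(UserWarning):
            record = summarize(matches, a, b, cells)
        assert record.coloc_per_cell is None

    def test_counts_consistency(self):
        labels = np.zeros((40, 40)); _square(labels, 5, 5, 8, 1)
        cells = count_cells(_mask_with(labels))
        rng = np.random.default_rng(4)
        matches, a, b = self._inputs(rng.uniform(0, 40, (6, 2)),
                                     rng.uniform(0, 40, (4, 2)))
        record = summarize(matches, a, b, cells)
        assert record.n_coloc <= min(record.n_particles_a, record.n_particles_b)

    def test_empty_tables_give_zero_statistic(self):
        labels = np.zeros((40, 40)); _square(labels, 5, 5, 8, 1)
        cells = count_cells(_mask_with(labels))
        empty = ParticleTable.empty()
        matches = match_particles(empty, empty, 4.0)
        record = summarize(matches, empty, empty, cells)
        assert record.n_coloc == 0 and record.coloc_per_cell == 0.0
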