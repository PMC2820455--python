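"""Segmentation and perinuclear ring measurement, audited by brute force."""

import numpy as np
import pytest
from skimage.draw import disk

from tauscreen.imagequant import (
    QuantConfig,
    aggregate_well,
    measure_cells,
    quantify_image,
    ring_mask,
    ring_owner_map,
    segment_nuclei,
)
from tauscreen.synth import Baselines, render_well_image

from conftest import QUIET, make_effect


# ---------------------------------------------------------------- oracles
def brute_force_rings(labels: np.ndarray, width: int) -> np.ndarray:
    """Independent ring assignment by direct distance enumeration.

    A non-nucleus pixel belongs to the ring of the nucleus within Chebyshev
    distance <= width whose centroid is nearest (Euclidean), ties to the
    lower label.
    """
    h, w = labels.shape
    labs = sorted(np.unique(labels[labels > 0]))
    coords = {l: np.argwhere(labels == l) for l in labs}
    cents = {l: coords[l].mean(axis=0) for l in labs}
    owner = np.zeros((h, w), dtype=int)
    for y in range(h):
        for x in range(w):
            if labels[y, x]:
                continue
            best_l, best_d = 0, np.inf
            for l in labs:
                cheb = np.max(np.abs(coords[l] - (y, x)), axis=1).min()
                if cheb <= width:
                    dc = (cents[l][0] - y) ** 2 + (cents[l][1] - x) ** 2
                    if dc < best_d:
                        best_l, best_d = l, dc
            owner[y, x] = best_l
    return owner


# ------------------------------------------------------------ segmentation
class TestSegmentNuclei:
    def test_uniform_image_yields_no_nuclei(self):
        assert segment_nuclei(np.full((64, 64), 37.0)).max() == 0
        assert segment_nuclei(np.zeros((64, 64))).max() == 0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            segment_nuclei(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            segment_nuclei(np.full((8, 8), -1.0))

    def test_recovers_rendered_nuclei_and_centroids(self):
        rw = render_well_image(make_effect(cells=5), QUIET, image_shape=(256, 256), seed=5)
        labels = segment_nuclei(rw.image[0].astype(float))
        assert labels.max() == len(rw.truth)
        from skimage.measure import regionprops

        found = sorted((p.centroid for p in regionprops(labels)))
        expected = sorted(zip(rw.truth["row"], rw.truth["col"]))
        for (fy, fx), (ty, tx) in zip(found, expected):
            assert np.hypot(fy - ty, fx - tx) < 1.0

    def test_watershed_splits_touching_disks(self):
        img = np.zeros((64, 64))
        for center in ((30, 25), (30, 39)):  # 30% overlap of radius-10 disks
            rr, cc = disk(center, 10)
            img[rr, cc] = 10_000
        assert segment_nuclei(img, split_touching=False).max() == 1
        assert segment_nuclei(img, split_touching=True).max() == 2

    def test_min_area_filter(self):
        img = np.zeros((64, 64))
        rr, cc = disk((20, 20), 10)
        img[rr, cc] = 5000
        rr, cc = disk((50, 50), 2.5)
        img[rr, cc] = 5000
        assert segment_nuclei(img, min_area=30, smoothing_sigma=1.0).max() == 1


# -------------------------------------------------------------------- ring
class TestRingGeometry:
    def test_point_nucleus_width4_ring_is_80_pixels(self):
        lab = np.zeros((21, 21), dtype=int)
        lab[10, 10] = 1
        ring = ring_mask(lab == 1, width=4)
        assert ring.sum() == 9 * 9 - 1  # 80, brute-force enumeration below
        ys, xs = np.nonzero(ring)
        cheb = np.maximum(np.abs(ys - 10), np.abs(xs - 10))
        assert cheb.max() == 4 and cheb.min() == 1

    def test_width_zero_rejected(self):
        lab = np.zeros((5, 5), dtype=bool)
        lab[2, 2] = True
        with pytest.raises(ValueError):
            ring_mask(lab, width=0)

    def test_ring_clipped_at_image_bounds(self):
        lab = np.zeros((6, 6), dtype=bool)
        lab[0, 0] = True
        ring = ring_mask(lab, width=4)
        assert ring.sum() == 5 * 5 - 1

    def test_euclidean_metric_is_disk(self):
        lab = np.zeros((21, 21), dtype=bool)
        lab[10, 10] = True
        ring = ring_mask(lab, width=4, metric="euclidean")
        yy, xx = np.mgrid[:21, :21]
        expected = ((yy - 10) ** 2 + (xx - 10) ** 2 <= 16) & ~lab
        assert np.array_equal(ring, expected)

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("width", [1, 4])
    def test_owner_map_matches_brute_force(self, seed, width):
        rng = np.random.default_rng(seed)
        labels = np.zeros((28, 28), dtype=np.int32)
        for lab in (1, 2, 3):
            cy, cx = rng.integers(4, 24, size=2)
            rr, cc = disk((cy, cx), rng.uniform(2, 4), shape=labels.shape)
            free = labels[rr, cc] == 0
            labels[rr[free], cc[free]] = lab
        owner, _ = ring_owner_map(labels, width=width)
        assert np.array_equal(owner, brute_force_rings(labels, width))

    def test_rings_exclude_all_nuclei_and_respect_distance(self):
        # two adjacent nuclei, 3 px apart: every ring pixel is off-nucleus
        # and within Chebyshev distance `width` of its own nucleus
        labels = np.zeros((24, 24), dtype=np.int32)
        labels[10:13, 5:8] = 1
        labels[10:13, 11:14] = 2
        owner, _ = ring_owner_map(labels, width=4)
        assert np.all(owner[labels > 0] == 0)
        for lab in (1, 2):
            ys, xs = np.nonzero(owner == lab)
            pix = np.argwhere(labels == lab)
            for y, x in zip(ys, xs):
                assert np.max(np.abs(pix - (y, x)), axis=1).min() <= 4
        assert np.array_equal(owner, brute_force_rings(labels, 4))


# ------------------------------------------------------------- measurement
class TestMeasureCells:
    def test_constant_channel_measures_constant(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[14:18, 14:18] = 1
        cells = measure_cells(labels, np.full((32, 32), 100.0), np.full((32, 32), 7.0))
        assert len(cells) == 1
        assert cells[0].mean_red == 100.0 and cells[0].mean_green == 7.0

    def test_shape_mismatch_is_hard_error(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        with pytest.raises(ValueError):
            measure_cells(labels, np.zeros((16, 16)), np.zeros((8, 8)))

    def test_corner_nucleus_flagged_border(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[0:3, 0:3] = 1
        labels[14:18, 14:18] = 2
        cells = measure_cells(labels, np.ones((32, 32)), np.ones((32, 32)))
        flags = {c.label: c.border_flag for c in cells}
        assert flags[1] and not flags[2]

    def test_quantitation_linearity(self, rng):
        labels = np.zeros((48, 48), dtype=np.int32)
        labels[10:16, 10:16] = 1
        labels[30:36, 28:34] = 2
        red = rng.uniform(0, 1000, (48, 48))
        green = rng.uniform(0, 1000, (48, 48))
        base = measure_cells(labels, red, green)
        scaled = measure_cells(labels, 3.5 * red, 0.25 * green)
        for b, s in zip(base, scaled):
            assert s.mean_red == pytest.approx(3.5 * b.mean_red, rel=1e-12)
            assert s.mean_green == pytest.approx(0.25 * b.mean_green, rel=1e-12)

    def test_noiseless_rendered_well_ratio_recovered_within_1pct(self):
        eff = make_effect(phospho=0.5, total=1.0, cells=20)
        rw = render_well_image(eff, QUIET, image_shape=(256, 256), seed=7)
        _, cells = quantify_image(rw.image)
        b = Baselines()
        for c in cells:
            assert c.mean_red / c.mean_green == pytest.approx(
                0.5 * b.phospho / b.total, rel=0.01
            )


class TestAggregateWell:
    def test_unweighted_mean(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        red = np.zeros((64, 64))
        for i, (y, val) in enumerate(zip((10, 30, 50), (1.0, 2.0, 3.0)), start=1):
            labels[y : y + 4, 30:34] = i
            red[y - 5 : y + 9, 25:39] = val
        cells = measure_cells(labels, red, red)
        wm = aggregate_well(cells, "P01r1", "A01", 1)
        assert wm.cell_count == 3
        assert wm.phospho_mean == pytest.approx(2.0)

    def test_empty_well_is_missing(self):
        wm = aggregate_well([], "P01r1", "A01", 1)
        assert wm.cell_count == 0 and np.isnan(wm.phospho_mean)

    def test_rendered_counts_within_poisson_band(self):
        # counts over wells stay inside the 95% Poisson band of the mean
        counts = []
        for seed in range(12):
            rw = render_well_image(make_effect(cells=40), QUIET, (256, 256), seed=seed)
            _, cells = quantify_image(rw.image)
            counts.append(aggregate_well(cells, "P", "W", 1).cell_count)
        lam = 40.0 * len(counts)
        total = sum(counts)
        assert abs(total - lam) < 1.96 * np.sqrt(lam)


def test_quantify_image_rejects_wrong_stack():
    with pytest.raises(ValueError):
        quantify_image(np.zeros((2, 32, 32)))


def test_quant_config_validation():
    with pytest.raises(ValueError):
        QuantConfig(ring_width=0)
    with pytest.raises(ValueError):
        QuantConfig(ring_metric="manhattan")
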