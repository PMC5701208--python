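"""Ground-truth generator: geometry, placement laws, rendering, determinism."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import ndimage, stats as sps

from pfl import (
    SynthParams,
    make_ground_truth,
    make_sample,
    place_foci,
    render_channels,
    sample_island_shapes,
)
from pfl.synth import nucleus_disc, place_foci_hardcore


def disc_mask(radius, pad=3):
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


class TestIslandShapes:
    def test_zero_islands_empty(self):
        p = SynthParams(n_islands=0)
        assert sample_island_shapes(p, np.random.default_rng(0)) == []

    def test_area_within_ten_percent(self):
        p = SynthParams(n_islands=1, island_area_range=(20.0, 20.0))
        m = sample_island_shapes(p, np.random.default_rng(1))[0]
        target = 20.0 / p.pixel_size**2
        assert 0.9 * target <= m.sum() <= 1.1 * target

    def test_disjoint_and_inside_nucleus(self):
        p = SynthParams(n_islands=3, island_area_range=(10.0, 16.0))
        masks = sample_island_shapes(p, np.random.default_rng(2))
        nucleus = nucleus_disc(p)
        assert len(masks) == 3
        union = np.zeros(p.image_shape, dtype=int)
        for m in masks:
            assert not (m & ~nucleus).any()
            union += m
        assert union.max() == 1  # pairwise disjoint
        # >= 2 px gap between islands
        for i, m in enumerate(masks):
            others = np.zeros(p.image_shape, bool)
            for j, m2 in enumerate(masks):
                if j != i:
                    others |= m2
            assert not (ndimage.binary_dilation(m, iterations=2) & others).any()

    def test_impossible_packing_raises(self):
        p = SynthParams(n_islands=12, island_area_range=(60.0, 80.0))
        with pytest.raises(RuntimeError):
            sample_island_shapes(p, np.random.default_rng(3))


class TestPlaceFoci:
    def test_zero_density_empty(self):
        assert place_foci(disc_mask(10), 0.0, 0.1, rng=np.random.default_rng(0)) == []

    def test_all_points_inside_mask(self):
        mask = disc_mask(10)
        pts = place_foci(mask, 5.0, 0.2, rng=np.random.default_rng(1))
        for r, c in pts:
            assert mask[int(np.floor(r + 0.5)), int(np.floor(c + 0.5))]

    def test_uniform_occupancy_flat_over_distance(self):
        """Chi-square GOF of distances of ~10k uniform points vs pixel counts."""
        mask = disc_mask(15)
        field = ndimage.distance_transform_edt(mask)
        rng = np.random.default_rng(2)
        pts = []
        while len(pts) < 10_000:
            pts += place_foci(mask, 6.0, 0.5, rng=rng)
        pts = pts[:10_000]
        d = np.array([field[int(np.floor(r + 0.5)), int(np.floor(c + 0.5))] for r, c in pts])
        bins = np.ceil(d).astype(int) - 1
        pix = np.bincount(np.ceil(field[field > 0]).astype(int) - 1)
        counts = np.bincount(bins, minlength=len(pix))
        expected = len(d) * pix / pix.sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert sps.chi2.sf(chi2, df=len(pix) - 1) > 0.01

    def test_boundary_bias_increases_mean_distance(self):
        mask = disc_mask(15)
        field = ndimage.distance_transform_edt(mask)
        rng = np.random.default_rng(3)

        def mean_d(mode, bias):
            pts = []
            while len(pts) < 2000:
                pts += place_foci(mask, 6.0, 0.5, mode, bias, rng)
            return np.mean(
                [field[int(np.floor(r + 0.5)), int(np.floor(c + 0.5))] for r, c in pts[:2000]]
            )

        assert mean_d("boundary_biased", 3.0) > mean_d("uniform", 0.0) + 1.0

    def test_hardcore_respects_min_spacing(self):
        mask = disc_mask(30)
        pts = np.array(place_foci_hardcore(mask, 2.0, 0.2, 0.5, np.random.default_rng(4)))
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert np.sqrt(d2.min()) >= 0.5 / 0.2  # min spacing in px


class TestRendering:
    def test_dark_generator_produces_all_zero_images(self):
        p = SynthParams(photon_scale=0.0, read_noise_sd=0.0, background=0.0, seed=5)
        a, b, _ = make_sample(p)
        assert a.max() == 0 and b.max() == 0

    def test_single_focus_argmax_at_focus_pixel(self):
        p = SynthParams(read_noise_sd=0.0, background=0.0, halo_fraction=0.0)
        truth = make_ground_truth(SynthParams(n_islands=0, seed=1), np.random.default_rng(1))
        truth.pore_rich_foci = [(60.3, 90.1)]
        truth.b_pore_region_foci = []
        rng = np.random.default_rng(0)
        # large photon budget suppresses relative shot noise at the peak
        a, _ = render_channels(truth, replace(p, photon_scale=1e4, n_islands=0), rng)
        r, c = np.unravel_index(np.argmax(a), a.shape)
        assert (r, c) == (60, 90)

    def test_bit_identical_given_seed(self):
        a1, b1, t1 = make_sample(SynthParams(seed=9))
        a2, b2, t2 = make_sample(SynthParams(seed=9))
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)
        assert all(np.array_equal(x, y) for x, y in zip(t1.island_masks, t2.island_masks))

    def test_islands_contain_no_channel_a_foci(self):
        _, _, truth = make_sample(SynthParams(seed=11))
        union = np.zeros(truth.nucleus_mask.shape, bool)
        for m in truth.island_masks:
            union |= m
        for r, c in truth.pore_rich_foci:
            assert not union[int(np.floor(r + 0.5)), int(np.floor(c + 0.5))]

    def test_island_foci_inside_their_islands(self):
        _, _, truth = make_sample(SynthParams(seed=12))
        for mask, foci in zip(truth.island_masks, truth.island_foci):
            for r, c in foci:
                assert mask[int(np.floor(r + 0.5)), int(np.floor(c + 0.5))]

    def test_bit_depth_and_dtype(self):
        a8, _, _ = make_sample(SynthParams(seed=1, bit_depth=8))
        a16, _, _ = make_sample(SynthParams(seed=1, bit_depth=16))
        assert a8.dtype == np.uint8 and a16.dtype == np.uint16
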