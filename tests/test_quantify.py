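"""Island metrics, distance fields, distance profiles and aggregation."""

import numpy as np
import pytest

from pfl import (
    aggregate_profiles,
    distance_field,
    distance_profile,
    island_metrics,
    split_proximal_distal,
)


def brute_force_edt(mask):
    """Minimum Euclidean distance to any background pixel (oracle)."""
    out = np.zeros(mask.shape)
    bg = np.argwhere(~mask)
    for i, j in np.argwhere(mask):
        d2 = ((bg - (i, j)) ** 2).sum(axis=1)
        out[i, j] = np.sqrt(d2.min())
    return out


class TestIslandMetrics:
    def test_area_and_frequency_arithmetic(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask.flat[:1000] = True
        rec = island_metrics(mask, 12, pixel_size=0.1)
        assert rec.area_px == 1000
        assert np.isclose(rec.area_um2, 10.0)
        assert np.isclose(rec.frequency, 1.2)

    def test_zero_foci_zero_frequency(self):
        rec = island_metrics(np.ones((5, 5), bool), 0, 1.0)
        assert rec.frequency == 0.0

    def test_density_scale_of_whole_roi_mode(self):
        # 256 foci over 100 um^2 -> 2.56 foci/um^2
        mask = np.ones((100, 100), dtype=bool)
        rec = island_metrics(mask, 256, pixel_size=0.1)
        assert np.isclose(rec.frequency, 2.56)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            island_metrics(np.zeros((4, 4), bool), 0, 1.0)


class TestDistanceField:
    def test_3x3_island_geometry(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[2:5, 2:5] = True
        f = distance_field(mask)
        rim = f[mask] == 1.0
        assert rim.sum() == 8
        assert f[3, 3] == 2.0
        assert np.all(f[~mask] == 0.0)

    def test_single_pixel_island(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert distance_field(mask)[2, 2] == 1.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            mask = rng.random((16, 16)) < 0.4
            mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
            if not mask.any():
                continue
            assert np.array_equal(distance_field(mask), brute_force_edt(mask))


class TestDistanceProfile:
    def test_center_focus_in_3x3_island(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[2:5, 2:5] = True
        f = distance_field(mask)
        prof = distance_profile([(3.0, 3.0)], f)
        assert np.array_equal(prof.pixel_counts, [8, 1])
        assert np.array_equal(prof.focus_counts, [0, 1])
        assert np.allclose(prof.raw_frequency, [0.0, 1.0])

    def test_no_foci_all_zero(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[2:5, 2:5] = True
        prof = distance_profile([], distance_field(mask))
        assert np.all(prof.focus_counts == 0)

    def test_count_conservation(self, rng):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True
        f = distance_field(mask)
        pix = np.argwhere(mask)
        foci = [tuple(pix[i] + rng.uniform(-0.4, 0.4, 2)) for i in rng.integers(0, len(pix), 17)]
        prof = distance_profile(foci, f)
        assert prof.focus_counts.sum() == 17

    def test_focus_outside_island_rejected(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[2:5, 2:5] = True
        with pytest.raises(ValueError):
            distance_profile([(0.0, 0.0)], distance_field(mask))


class TestAggregateProfiles:
    def _profile(self, side, foci):
        mask = np.zeros((side + 4, side + 4), dtype=bool)
        mask[2 : 2 + side, 2 : 2 + side] = True
        return distance_profile(foci, distance_field(mask))

    def test_single_profile_normalizes_to_one(self):
        prof = self._profile(5, [(4.0, 4.0), (2.0, 3.0)])
        agg = aggregate_profiles([prof])
        assert np.isclose(agg.normalized_frequency.sum(), 1.0, atol=1e-9)

    def test_two_identical_profiles_idempotent(self):
        p = self._profile(5, [(4.0, 4.0)])
        one = aggregate_profiles([p])
        two = aggregate_profiles([p, p])
        assert np.allclose(one.normalized_frequency, two.normalized_frequency)

    def test_islands_contribute_only_their_own_bins(self):
        small = self._profile(3, [(3.0, 3.0)])
        big = self._profile(9, [(6.0, 6.0)])
        agg = aggregate_profiles([small, big])
        assert agg.n_bins == big.n_bins
        # beyond the small island's depth only the big island is averaged
        assert np.allclose(
            agg.raw_frequency[small.n_bins :], big.raw_frequency[small.n_bins :]
        )

    def test_all_empty_profiles_flagged_not_error(self):
        p = self._profile(5, [])
        agg = aggregate_profiles([p, p])
        assert agg.normalized_frequency is None


class TestSplitProximalDistal:
    def _dummy(self, n_bins):
        edges = np.arange(n_bins + 1, dtype=float)
        z = np.zeros(n_bins)
        from pfl import DistanceProfile

        return DistanceProfile(edges, z, z.astype(int) + 1, z)

    def test_ten_bins_half_split(self):
        prox, dist = split_proximal_distal(self._dummy(10), 0.5)
        assert list(prox) == [0, 1, 2, 3, 4]
        assert list(dist) == [5, 6, 7, 8, 9]

    def test_three_bins_floor_rule(self):
        prox, dist = split_proximal_distal(self._dummy(3), 0.5)
        assert list(prox) == [0]
        assert list(dist) == [1, 2]

    def test_partition_property(self):
        for n in (1, 2, 5, 9):
            prox, dist = split_proximal_distal(self._dummy(n), 0.4)
            assert sorted(list(prox) + list(dist)) == list(range(n))
            assert len(prox) >= 1

    def test_single_bin_distal_empty(self):
        prox, dist = split_proximal_distal(self._dummy(1), 0.5)
        assert list(prox) == [0] and len(dist) == 0
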