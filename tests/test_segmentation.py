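"""K-means clustering, WCV trace, cluster-number rule, island extraction."""

import numpy as np
import pytest

from pfl import (
    KSelectionTrace,
    cluster_pixels,
    extract_islands,
    select_island_class,
    select_k,
    wcv_trace,
)


def make_trace(totals, k0=2):
    totals = np.asarray(totals, dtype=float)
    ks = list(range(k0, k0 + len(totals)))
    return KSelectionTrace(
        ks, np.zeros((len(ks), 3)), np.zeros((len(ks), 3)), totals, np.diff(totals)
    )


class TestSelectK:
    def test_sign_change_selects_local_minimum(self):
        # diffs [-3, -1, +0.5, +0.5] -> minimum at k=4
        assert select_k(make_trace([10, 7, 6, 6.5, 7])) == 4

    def test_monotone_decreasing_falls_back_to_argmin(self):
        trace = make_trace(np.linspace(10, 1, 19))
        assert select_k(trace) == 20
        assert trace.fallback

    def test_plateau_minimum_selects_plateau_start(self):
        # diffs [-1, 0, +1]: the plateau 6,6 starts at k=3
        assert select_k(make_trace([7, 6, 6, 7])) == 3

    def test_initial_rise_then_minimum(self):
        # rise first, then a genuine minimum at k=5
        assert select_k(make_trace([5, 6, 4, 3, 4])) == 5

    def test_too_few_k_values_rejected(self):
        with pytest.raises(ValueError):
            select_k(make_trace([3, 2]))


class TestClusterPixels:
    def test_separable_clouds_partition_exactly(self, rng):
        valid = np.ones((10, 10), dtype=bool)
        feats = np.zeros((10, 10, 3))
        feats[:5] = 10.0 + rng.normal(0, 0.1, size=(5, 10, 3))
        feats[5:] = -10.0 + rng.normal(0, 0.1, size=(5, 10, 3))
        lm = cluster_pixels(feats, valid, 2, seed=0)
        assert len(np.unique(lm[:5])) == 1
        assert len(np.unique(lm[5:])) == 1
        assert lm[0, 0] != lm[9, 9]

    def test_identical_features_degenerate(self):
        valid = np.ones((6, 6), dtype=bool)
        feats = np.ones((6, 6, 3))
        lm = cluster_pixels(feats, valid, 2, seed=0)
        # degenerate clusters tolerated; every pixel gets a label
        assert set(np.unique(lm)) <= {0, 1}

    def test_deterministic_given_seed(self, rng):
        valid = np.ones((12, 12), dtype=bool)
        feats = rng.normal(size=(12, 12, 3))
        a = cluster_pixels(feats, valid, 3, seed=7)
        b = cluster_pixels(feats, valid, 3, seed=7)
        assert np.array_equal(a, b)

    def test_k_exceeding_pixels_rejected(self):
        valid = np.zeros((4, 4), dtype=bool)
        valid[0, :2] = True
        with pytest.raises(ValueError):
            cluster_pixels(np.zeros((4, 4, 3)), valid, 3)


class TestSelectIslandClass:
    def test_lowest_mean_intensity_wins(self):
        lm = np.array([[0, 0], [1, 1]])
        img = np.array([[200.0, 200.0], [20.0, 20.0]])
        assert select_island_class(lm, img) == 1

    def test_tie_breaks_to_lower_label(self):
        lm = np.array([[0, 1]])
        img = np.array([[5.0, 5.0]])
        assert select_island_class(lm, img) == 0


class TestWcvTrace:
    def test_matches_loop_variance_oracle(self, rng):
        feats = rng.normal(size=(10, 10, 3))
        valid = np.ones((10, 10), dtype=bool)
        img = rng.uniform(0, 10, size=(10, 10))
        lms = {k: cluster_pixels(feats, valid, k, seed=1) for k in (2, 3, 4)}
        tr = wcv_trace(feats, lms, img)
        for i, k in enumerate((2, 3, 4)):
            cls = select_island_class(lms[k], img)
            px = feats[lms[k] == cls]
            for f in range(3):
                expected = np.mean((px[:, f] - px[:, f].mean()) ** 2)
                assert abs(tr.wcv_per_feature[i, f] - expected) < 1e-10

    def test_normalized_in_unit_interval_with_extremes(self, rng):
        feats = rng.normal(size=(12, 12, 3))
        valid = np.ones((12, 12), dtype=bool)
        img = rng.uniform(0, 10, size=(12, 12))
        lms = {k: cluster_pixels(feats, valid, k, seed=1) for k in range(2, 7)}
        tr = wcv_trace(feats, lms, img)
        assert np.all(tr.wcv_normalized >= 0) and np.all(tr.wcv_normalized <= 1)
        for f in range(3):
            col = tr.wcv_normalized[:, f]
            if np.ptp(tr.wcv_per_feature[:, f]) > 0:
                assert np.isclose(col.min(), 0) and np.isclose(col.max(), 1)


class TestExtractIslands:
    def test_empty_island_class(self):
        lm = np.zeros((8, 8), dtype=np.int32)
        masks, bounds, n = extract_islands(lm, 5, np.ones((8, 8), bool))
        assert masks == [] and bounds == [] and n == 0

    def test_single_blob_with_boundary(self):
        lm = np.zeros((20, 20), dtype=np.int32)
        lm[5:15, 5:15] = 1
        masks, bounds, n = extract_islands(
            lm, 1, np.ones((20, 20), bool), min_island_area_px=10, drop_border=False
        )
        assert n == 1 and len(masks) == 1
        # boundary = island pixels 4-adjacent to non-island pixels
        m, b = masks[0], bounds[0]
        assert b.sum() < m.sum()
        assert np.all(m[b])
        interior = m & ~b
        assert not np.any(interior[5, :]) and not np.any(interior[:, 5])

    def test_small_components_filtered(self):
        lm = np.zeros((20, 20), dtype=np.int32)
        lm[2:5, 2:5] = 1  # 9 px speckle (survives opening, fails area filter)
        lm[8:16, 8:16] = 1  # 64 px island
        masks, _, n = extract_islands(
            lm, 1, np.ones((20, 20), bool), min_island_area_px=20, drop_border=False
        )
        assert n == 2 and len(masks) == 1
        assert masks[0].sum() >= 60
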