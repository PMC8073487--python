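"""Postprocessing: reflections, distance map, region growing, decision."""

import numpy as np
import pytest

from viadyn.postprocess import (ProbabilityMap, close_regions, decide_sequence,
                                make_distance_map, modulate,
                                neutralize_reflections, region_growing)


def flood_fill_oracle(probs, seed, taken, homogeneity_thr, min_prob):
    """Brute-force fixpoint: repeatedly sweep the whole grid adding any
    4-neighbor of the region that satisfies the dual predicate (anchored
    to the seed's probability)."""
    H, W = probs.shape
    region = np.zeros((H, W), bool)
    region[seed] = True
    seed_prob = probs[seed]
    changed = True
    while changed:
        changed = False
        for r in range(H):
            for c in range(W):
                if region[r, c] or taken[r, c]:
                    continue
                p = probs[r, c]
                if not (abs(seed_prob - p) < homogeneity_thr and p > min_prob):
                    continue
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < H and 0 <= nc < W and region[nr, nc]:
                        region[r, c] = True
                        changed = True
                        break
    return region


def oracle_region_growing(probs, n_seeds, homogeneity_thr, min_prob, rng_seed,
                          seed_top_fraction=0.005):
    """Full seeded-growth oracle mirroring the documented seed schedule."""
    rng = np.random.default_rng(rng_seed)
    H, W = probs.shape
    labels = np.zeros((H, W), int)
    taken = np.zeros((H, W), bool)
    label = 1
    for k in range(n_seeds):
        if k == 0:
            cutoff = np.quantile(probs, 1 - seed_top_fraction)
            cand = np.argwhere(probs >= cutoff)
            seed = tuple(cand[rng.integers(len(cand))])
        else:
            masked = np.where(taken, -np.inf, probs)
            flat = int(np.argmax(masked))
            seed = (flat // W, flat % W)
        if probs[seed] <= min_prob:
            break
        region = flood_fill_oracle(probs, seed, taken, homogeneity_thr, min_prob)
        taken |= region
        labels[region] = label
        label += 1
    return labels


def _pmap(probs, refl=None):
    probs = np.asarray(probs, float)
    refl = np.zeros_like(probs, bool) if refl is None else refl
    return ProbabilityMap(probs, refl)


class TestNeutralizeReflections:
    def test_flagged_pixels_set_to_half(self):
        refl = np.zeros((3, 3), bool)
        refl[1, 1] = True
        probs = np.full((3, 3), 0.99)
        out = neutralize_reflections(_pmap(probs, refl))
        assert out.probs[1, 1] == 0.5

    def test_unflagged_pixels_bit_identical(self):
        rng = np.random.default_rng(0)
        probs = rng.random((5, 5))
        refl = rng.random((5, 5)) > 0.7
        out = neutralize_reflections(_pmap(probs, refl))
        assert np.array_equal(out.probs[~refl], probs[~refl])

    def test_empty_mask_unchanged(self):
        probs = np.random.default_rng(1).random((4, 4))
        out = neutralize_reflections(_pmap(probs))
        assert np.array_equal(out.probs, probs)


class TestDistanceMap:
    def test_center_weight_is_one(self):
        dmap = make_distance_map((21, 21))
        assert dmap.weights[10, 10] == pytest.approx(1.0)

    def test_farthest_point_weight_is_half(self):
        dmap = make_distance_map((21, 31))
        assert dmap.weights.min() == pytest.approx(0.5)
        assert dmap.weights[0, 0] == pytest.approx(0.5)  # a farthest corner

    def test_midway_point_is_three_quarters(self):
        """weight = 1 - 0.5 * d / d_max, so d = d_max/2 gives 0.75."""
        dmap = make_distance_map((1, 101), center=(0, 0))
        assert dmap.weights[0, 50] == pytest.approx(0.75)

    def test_radially_non_increasing(self):
        dmap = make_distance_map((41, 41))
        c = 20
        row = dmap.weights[c, c:]
        assert np.all(np.diff(row) <= 1e-12)

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            make_distance_map((10, 10), center=(20, 5))


class TestModulate:
    def test_elementwise_product(self):
        dmap = make_distance_map((1, 101), center=(0, 0))
        probs = np.full((1, 101), 0.8)
        out = modulate(_pmap(probs), dmap)
        assert out.probs[0, 50] == pytest.approx(0.6)  # 0.8 * 0.75

    def test_never_increases_probability(self):
        rng = np.random.default_rng(2)
        probs = rng.random((20, 20))
        out = modulate(_pmap(probs), make_distance_map((20, 20)))
        assert np.all(out.probs <= probs + 1e-15)

    def test_central_blob_survives_peripheral_attenuated(self):
        probs = np.zeros((61, 61))
        probs[28:33, 28:33] = 0.9  # central blob
        probs[1:6, 1:6] = 0.9      # identical peripheral blob
        out = modulate(_pmap(probs), make_distance_map((61, 61)))
        assert out.probs[30, 30] > out.probs[3, 3]
        assert out.probs[30, 30] > 0.85 and out.probs[3, 3] < 0.55


class TestRegionGrowing:
    def test_uniform_high_map_single_region_fills_grid(self):
        labels = region_growing(np.full((10, 10), 0.9), n_seeds=1, rng_seed=0)
        assert np.all(labels == 1)

    def test_two_plateaus_only_high_one_grows(self):
        probs = np.zeros((10, 20))
        probs[:, :8] = 0.9
        probs[:, 12:] = 0.3
        labels = region_growing(probs, n_seeds=1, rng_seed=1)
        assert np.all(labels[:, :8] == 1)
        assert np.all(labels[:, 8:] == 0)

    def test_all_low_map_gives_zero_regions(self):
        labels = region_growing(np.full((8, 8), 0.5), n_seeds=5, rng_seed=0)
        assert not labels.any()

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_flood_fill_oracle_on_random_maps(self, trial):
        """Implementation equals the brute-force oracle with the identical
        dual predicate on random smooth maps."""
        rng = np.random.default_rng(trial)
        from scipy.ndimage import gaussian_filter
        probs = gaussian_filter(rng.random((24, 24)), 2)
        probs = (probs - probs.min()) / (probs.max() - probs.min())
        labels = region_growing(probs, n_seeds=3, rng_seed=trial)
        expected = oracle_region_growing(probs, 3, 0.27, 0.50, trial)
        assert np.array_equal(labels, expected)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        probs = rng.random((30, 30))
        a = region_growing(probs, rng_seed=42)
        b = region_growing(probs, rng_seed=42)
        assert np.array_equal(a, b)


class TestCloseRegions:
    def test_solid_rectangle_unchanged(self):
        labels = np.zeros((30, 30), int)
        labels[5:20, 5:20] = 1
        assert np.array_equal(close_regions(labels), labels)

    def test_interior_hole_filled(self):
        labels = np.zeros((30, 30), int)
        labels[5:20, 5:20] = 1
        labels[10:13, 10:13] = 0  # 3x3 hole
        closed = close_regions(labels, kernel=7)
        assert np.all(closed[5:20, 5:20] == 1)

    def test_distant_regions_not_merged(self):
        labels = np.zeros((30, 60), int)
        labels[10:20, 5:15] = 1
        labels[10:20, 35:45] = 2  # 20 px gap
        closed = close_regions(labels, kernel=7)
        assert set(np.unique(closed)) == {0, 1, 2}
        assert not closed[:, 20:30].any()

    def test_matches_brute_force_closing_oracle(self):
        """Closing = dilation then erosion with the same 7x7 kernel on the
        infinite plane; checked against direct offset-stack arithmetic on
        a padded grid."""
        rng = np.random.default_rng(5)
        mask = rng.random((40, 40)) > 0.6
        labels = mask.astype(int)

        def brute(mask, k, op):
            r = k // 2
            H, W = mask.shape
            padded = np.pad(mask, r, constant_values=False)
            stacks = np.stack([padded[r + dy : r + dy + H, r + dx : r + dx + W]
                               for dy in range(-r, r + 1)
                               for dx in range(-r, r + 1)])
            return stacks.any(0) if op == "dilate" else stacks.all(0)

        work = np.pad(mask, 3, constant_values=False)  # room for the dilation
        expected = brute(brute(work, 7, "dilate"), 7, "erode")[3:-3, 3:-3]
        result = close_regions(labels, 7) > 0
        assert np.array_equal(result, expected)
        # closing is extensive: every original pixel survives
        assert np.all(result[mask])


class TestDecideSequence:
    def _labels(self, size):
        labels = np.zeros((100, 100), int)
        labels.flat[:size] = 1
        return labels

    @pytest.mark.parametrize("size,decision", [(450, "positive"),
                                               (449, "negative")])
    def test_size_threshold_boundary(self, size, decision):
        pred = decide_sequence(self._labels(size), 450)
        assert pred.decision == decision

    def test_no_regions_is_negative(self):
        pred = decide_sequence(np.zeros((10, 10), int))
        assert pred.decision == "negative"
        assert pred.region_sizes == {}

    def test_monotone_in_region_size(self):
        """Adding pixels to a region can never flip positive -> negative."""
        small = self._labels(449)
        grown = self._labels(700)
        assert decide_sequence(small, 450).decision == "negative"
        assert decide_sequence(grown, 450).decision == "positive"

    def test_contours_reported_for_regions(self):
        labels = np.zeros((20, 20), int)
        labels[5:15, 5:15] = 1
        pred = decide_sequence(labels, 450)
        assert 1 in pred.contours and len(pred.contours[1]) >= 1
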