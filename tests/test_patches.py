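"""Patch extraction, entropy ranking, image assembly, grid baseline, diagnostics."""

import numpy as np
import pytest

from msimg import (
    GoldenLocations,
    MultiChannelImage,
    PatchSpec,
    build_multichannel_image,
    extract_patch,
    grid_candidate_locations,
    inter_channel_correlation,
    patch_entropy,
    pca_components_for_variance,
    rank_golden_locations,
)
from tests.conftest import make_normalized


def bruteforce_patch(vals, center, spec):
    """Per-cell bounds-check extraction oracle."""
    h, w = spec.patch_height, spec.patch_width
    out = np.full((h, w), spec.pad_value)
    for i in range(h):
        for j in range(w):
            r = center[0] - h // 2 + i
            c = center[1] - w // 2 + j
            if 0 <= r < vals.shape[0] and 0 <= c < vals.shape[1]:
                out[i, j] = vals[r, c]
    return out


class TestExtractPatch:
    def test_interior_center_is_pure_slice(self, rng):
        vals = rng.uniform(size=(40, 40))
        patch = extract_patch(vals, (20, 20), PatchSpec(5, 7))
        np.testing.assert_array_equal(patch, vals[18:23, 17:24])

    def test_corner_center_pads_top_left(self, rng):
        vals = rng.uniform(size=(30, 30))
        patch = extract_patch(vals, (0, 0), PatchSpec(8, 8, pad_value=0.0))
        assert patch.shape == (8, 8)
        np.testing.assert_array_equal(patch[:4, :], 0.0)
        np.testing.assert_array_equal(patch[:, :4], 0.0)
        np.testing.assert_array_equal(patch[4:, 4:], vals[:4, :4])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_cell_oracle_near_borders(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(size=(25, 31))
        spec = PatchSpec(int(rng.integers(2, 12)), int(rng.integers(2, 12)), pad_value=0.25)
        for _ in range(20):
            edge_r = int(rng.choice([0, 1, 2, 24, 23, 12]))
            edge_c = int(rng.choice([0, 1, 2, 30, 29, 15]))
            np.testing.assert_array_equal(
                extract_patch(vals, (edge_r, edge_c), spec), bruteforce_patch(vals, (edge_r, edge_c), spec)
            )

    def test_center_outside_matrix_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            extract_patch(np.zeros((5, 5)), (5, 0), PatchSpec(3, 3))


class TestPatchEntropy:
    def test_constant_patch_zero_bits(self):
        assert patch_entropy(np.full((10, 10), 0.4)) == pytest.approx(0.0, abs=1e-12)

    def test_two_equiprobable_levels_one_bit(self):
        patch = np.zeros((8, 8))
        patch[:, 4:] = 1.0
        assert patch_entropy(patch) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_256_levels_eight_bits(self):
        patch = (np.arange(256) / 255.0).reshape(16, 16)
        assert patch_entropy(patch) == pytest.approx(8.0, abs=1e-12)

    def test_bounds_hold_for_random_patches(self, rng):
        for _ in range(20):
            h = patch_entropy(rng.uniform(size=(12, 12)))
            assert 0.0 <= h <= 8.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            patch_entropy(np.array([[0.5, 1.5]]))


class TestRankGoldenLocations:
    def test_single_sample_argmax(self):
        vals = np.zeros((40, 40))
        vals[10, 10] = 1.0  # 2-level patch -> positive entropy
        m = make_normalized(vals)
        golden = rank_golden_locations([m], [(30, 30), (10, 10)], PatchSpec(5, 5), 1)
        assert golden.locations == [(10, 10)]
        assert golden.mean_entropies[0] > 0

    def test_identical_samples_mean_equals_single(self, rng):
        vals = rng.uniform(size=(30, 30))
        mats = [make_normalized(vals)] * 4
        centers = [(5, 5), (15, 15), (25, 25)]
        golden = rank_golden_locations(mats, centers, PatchSpec(7, 7), 3)
        single = rank_golden_locations(mats[:1], centers, PatchSpec(7, 7), 3)
        assert golden.locations == single.locations
        np.testing.assert_allclose(golden.mean_entropies, single.mean_entropies)

    def test_matches_recompute_and_sort_oracle(self, rng):
        mats = [make_normalized(rng.uniform(size=(40, 50))) for _ in range(5)]
        centers = [(int(r), int(c)) for r, c in rng.integers(5, 35, size=(10, 2))]
        spec = PatchSpec(6, 6)
        golden = rank_golden_locations(mats, centers, spec, 10)
        table = {
            ctr: np.mean([patch_entropy(extract_patch(m, ctr, spec)) for m in mats]) for ctr in centers
        }
        expected = sorted(centers, key=lambda ctr: -table[ctr])  # stable: ties keep candidate order
        assert golden.locations == expected
        assert golden.mean_entropies == sorted(golden.mean_entropies, reverse=True)

    def test_too_many_patches_reports_achievable_maximum(self, rng):
        m = make_normalized(rng.uniform(size=(20, 20)))
        with pytest.raises(ValueError, match="achievable maximum is 2"):
            rank_golden_locations([m], [(5, 5), (10, 10)], PatchSpec(3, 3), 3)


class TestBuildMultichannelImage:
    def test_single_location_adds_unit_axis(self, rng):
        vals = rng.uniform(size=(30, 30))
        golden = GoldenLocations([(12, 14)], [1.0])
        img = build_multichannel_image(make_normalized(vals), golden, PatchSpec(5, 5))
        assert img.tensor.shape == (1, 5, 5)
        np.testing.assert_array_equal(img.tensor[0], extract_patch(vals, (12, 14), PatchSpec(5, 5)))

    def test_permuting_locations_permutes_channels(self, rng):
        vals = rng.uniform(size=(30, 30))
        locs = [(5, 5), (15, 15), (25, 25)]
        g1 = GoldenLocations(locs, [3.0, 2.0, 1.0])
        g2 = GoldenLocations(locs[::-1], [1.0, 2.0, 3.0])
        m = make_normalized(vals)
        t1 = build_multichannel_image(m, g1, PatchSpec(4, 4)).tensor
        t2 = build_multichannel_image(m, g2, PatchSpec(4, 4)).tensor
        np.testing.assert_array_equal(t1, t2[::-1])

    def test_channels_equal_independent_extractions(self, small_corpus):
        m = small_corpus[0][0]
        locs = [(20, 20), (64, 64), (100, 40)]
        golden = GoldenLocations(locs, [1.0, 1.0, 1.0])
        spec = PatchSpec(9, 9)
        img = build_multichannel_image(m, golden, spec)
        for ch, loc in enumerate(locs):
            np.testing.assert_array_equal(img.tensor[ch], extract_patch(m, loc, spec))

    def test_out_of_bounds_location_is_provenance_error(self):
        golden = GoldenLocations([(100, 100)], [1.0])
        with pytest.raises(ValueError, match="provenance"):
            build_multichannel_image(make_normalized(np.zeros((10, 10))), golden, PatchSpec(3, 3))


class TestGridCandidates:
    @pytest.mark.parametrize(
        "rows,cols,size,stride,expected_n",
        [(224, 224, 224, 224, 1), (448, 224, 224, 224, 2), (100, 100, 30, 10, 64)],
    )
    def test_location_count(self, rows, cols, size, stride, expected_n):
        locs = grid_candidate_locations(rows, cols, PatchSpec(size, size), stride)
        assert len(locs) == expected_n

    def test_closed_form_count_random_shapes(self, rng):
        import warnings

        for _ in range(15):
            rows, cols = int(rng.integers(10, 200)), int(rng.integers(10, 200))
            h, w = int(rng.integers(2, 40)), int(rng.integers(2, 40))
            s = int(rng.integers(1, 30))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                locs = grid_candidate_locations(rows, cols, PatchSpec(h, w), s)
            if h > rows or w > cols:
                assert locs == []
            else:
                assert len(locs) == ((rows - h) // s + 1) * ((cols - w) // s + 1)

    def test_row_major_from_top_left(self):
        locs = grid_candidate_locations(8, 8, PatchSpec(4, 4), 4)
        assert locs == [(2, 2), (2, 6), (6, 2), (6, 6)]

    def test_oversized_patch_warns_empty(self):
        with pytest.warns(RuntimeWarning, match="larger than matrix"):
            assert grid_candidate_locations(10, 10, PatchSpec(20, 20)) == []


def loop_pearson(x, y):
    mx, my = sum(x) / len(x), sum(y) / len(y)
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = sum((a - mx) ** 2 for a in x) ** 0.5
    sy = sum((b - my) ** 2 for b in y) ** 0.5
    return cov / (sx * sy)


class TestDiagnostics:
    def test_duplicated_channel_correlates_perfectly(self, rng):
        imgs = []
        for _ in range(6):
            a = rng.uniform(size=(4, 4))
            imgs.append(np.stack([a, a, rng.uniform(size=(4, 4))]))
        corr = inter_channel_correlation(imgs)
        assert corr[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert corr.shape == (3, 3)
        np.testing.assert_allclose(corr, corr.T)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_matches_loop_pearson(self, rng):
        imgs = [rng.uniform(size=(3, 2, 2)) for _ in range(5)]
        corr = inter_channel_correlation(imgs)
        flat = np.stack(imgs).transpose(1, 0, 2, 3).reshape(3, -1)
        for a in range(3):
            for b in range(3):
                assert corr[a, b] == pytest.approx(loop_pearson(flat[a], flat[b]), abs=1e-12)

    def test_constant_channel_reported_as_zero(self, rng):
        imgs = [np.stack([np.full((3, 3), 0.5), rng.uniform(size=(3, 3))]) for _ in range(4)]
        with pytest.warns(RuntimeWarning, match="constant"):
            corr = inter_channel_correlation(imgs)
        assert corr[0, 1] == 0.0 and corr[0, 0] == 1.0

    def test_rank_one_data_needs_one_component(self, rng):
        # second channel is a scaled copy of the first -> channel space is rank 1
        imgs = []
        for _ in range(4):
            a = rng.uniform(size=(4, 4))
            imgs.append(np.stack([a, 0.5 * a]))
        assert pca_components_for_variance(imgs, 0.95) == 1

    def test_matches_covariance_eigen_oracle(self, rng):
        imgs = [rng.uniform(size=(6, 5, 5)) for _ in range(8)]
        k = pca_components_for_variance(imgs, 0.9)
        X = np.stack(imgs).transpose(0, 2, 3, 1).reshape(-1, 6)
        Xc = X - X.mean(0)
        eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        cum = np.cumsum(eig) / eig.sum()
        expected = int(np.searchsorted(cum, 0.9) + 1)
        assert k == expected
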