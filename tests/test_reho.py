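from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

from rehopipe.images import Bold4D, BrainMask
from rehopipe.reho import (
    fwhm_to_sigma,
    kcc,
    neighborhood_offsets,
    reho_map,
    smooth_gaussian,
    standardize,
)


def kcc_bruteforce(x):
    """Independent rank-formula implementation: explicit mid-ranks by
    sorting and explicit (t^3 - t) tie-group counting, pure Python."""
    k, n = x.shape
    ranks = []
    for row in x:
        order = sorted(range(n), key=lambda i: row[i])
        r = [0.0] * n
        i = 0
        while i < n:
            j = i
            while j + 1 < n and row[order[j + 1]] == row[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        ranks.append(r)
    big_r = [sum(ranks[a][t] for a in range(k)) for t in range(n)]
    mean_r = sum(big_r) / n
    s = sum((v - mean_r) ** 2 for v in big_r)
    tie_sum = 0.0
    for row in x:
        for c in Counter(row.tolist()).values():
            tie_sum += c**3 - c
    denom = k * k * (n**3 - n) - k * tie_sum
    return 12.0 * s / denom if denom > 0 else 0.0


class TestKCC:
    def test_identical_monotone_series_give_one(self, rng):
        base = np.sort(rng.standard_normal(15))
        assert kcc(np.tile(base, (5, 1))) == pytest.approx(1.0, abs=1e-12)

    def test_two_reversed_series_give_zero(self):
        assert kcc(np.array([[1, 2, 3, 4], [4, 3, 2, 1]])) == pytest.approx(0.0, abs=1e-12)

    def test_three_by_three_example(self):
        x = np.array([[1, 2, 3], [1, 3, 2], [2, 1, 3]])
        assert kcc(x) == pytest.approx(4 / 9, abs=1e-12)
        assert kcc_bruteforce(x) == pytest.approx(4 / 9, abs=1e-12)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for trial in range(200):
            k = int(rng.integers(2, 9))
            n = int(rng.integers(3, 31))
            if trial % 2:
                x = rng.integers(0, max(2, n // 2), size=(k, n)).astype(float)  # ties
            else:
                x = rng.standard_normal((k, n))
            assert kcc(x) == pytest.approx(kcc_bruteforce(x), abs=1e-12)

    def test_friedman_cross_check_tie_free(self, rng):
        # W = chi2_F / (K (n - 1)) for the Friedman statistic of the same data
        from scipy.stats import friedmanchisquare

        x = rng.standard_normal((6, 12))
        chi2, _ = friedmanchisquare(*[x[:, t] for t in range(12)])
        assert kcc(x) == pytest.approx(chi2 / (6 * 11), rel=1e-10)

    @pytest.mark.parametrize("k", [2, 3, 5])
    @pytest.mark.parametrize("n", [5, 20])
    def test_equals_mean_pairwise_spearman_identity(self, rng, k, n):
        x = rng.standard_normal((k, n))
        rhos = [spearmanr(x[a], x[b]).statistic for a in range(k) for b in range(a + 1, k)]
        rho_bar = np.mean(rhos)
        assert kcc(x) == pytest.approx(((k - 1) * rho_bar + 1) / k, abs=1e-10)

    def test_null_mean_is_one_over_k(self, rng):
        k, n, reps = 5, 20, 2000
        w = np.array([kcc(rng.standard_normal((k, n))) for _ in range(reps)])
        se = w.std() / np.sqrt(reps)
        assert abs(w.mean() - 1 / k) < 3 * se

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
    def test_invariant_under_monotone_transform_of_one_series(self, shift, scale):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((4, 12))
        y = x.copy()
        y[2] = scale * np.exp(x[2] * 0.5) + shift  # strictly monotone in x[2]
        assert kcc(y) == pytest.approx(kcc(x), abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="series"):
            kcc(np.ones((1, 5)))
        with pytest.raises(ValueError, match="time points"):
            kcc(np.ones((3, 1)))
        with pytest.warns(UserWarning, match="constant"):
            assert kcc(np.ones((3, 5))) == 0.0


class TestRehoMap:
    def test_neighborhood_sizes(self):
        assert len(neighborhood_offsets(7)) == 7
        assert len(neighborhood_offsets(19)) == 19
        assert len(neighborhood_offsets(27)) == 27

    def test_uniform_monotone_volume_gives_one_everywhere(self, make_bold, full_mask):
        series = np.linspace(0, 1, 20)
        bold = make_bold(np.tile(series, (6, 6, 6, 1)))
        rmap = reho_map(bold, full_mask((6, 6, 6)))
        assert rmap.values[rmap.valid_mask] == pytest.approx(1.0, abs=1e-12)

    def test_null_mean_near_one_over_27(self, affine3mm, rng):
        bold = Bold4D(rng.standard_normal((13, 13, 13, 170)), affine3mm, 3.0)
        rmap = reho_map(bold, BrainMask.full((13, 13, 13), affine3mm))
        # stride-3 interior lattice: disjoint neighbourhoods, independent W
        lattice = rmap.values[2:-2:3, 2:-2:3, 2:-2:3].ravel()
        se = lattice.std() / np.sqrt(lattice.size)
        assert abs(lattice.mean() - 1 / 27) < 3 * se

    def test_single_voxel_mask_flagged_zero(self, make_bold, affine3mm, rng):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        bold = make_bold(rng.standard_normal((5, 5, 5, 10)))
        rmap = reho_map(bold, BrainMask(mask, affine3mm))
        assert rmap.flagged[2, 2, 2]
        assert rmap.values[2, 2, 2] == 0.0

    def test_grid_mismatch_is_an_error(self, make_bold, affine3mm, rng):
        bold = make_bold(rng.standard_normal((5, 5, 5, 10)))
        with pytest.raises(ValueError, match="grid"):
            reho_map(bold, BrainMask.full((6, 6, 6), affine3mm))

    def test_time_shuffling_destroys_planted_synchrony(self, affine3mm, rng):
        shared = rng.standard_normal(60)
        data = 0.5 * rng.standard_normal((8, 8, 8, 60)) + 0.9 * shared
        bold = Bold4D(data, affine3mm, 3.0)
        mask = BrainMask.full((8, 8, 8), affine3mm)
        w_sync = reho_map(bold, mask).values[4, 4, 4]
        # independent shuffle per voxel breaks the common signal
        shuffled = np.stack(
            [rng.permutation(s) for s in data.reshape(-1, 60)]
        ).reshape(data.shape)
        w_null = reho_map(Bold4D(shuffled, affine3mm, 3.0), mask).values[4, 4, 4]
        assert w_sync > 0.5
        assert w_null < 2 / 27  # back near the 1/K null level

    def test_map_values_match_direct_kcc_at_a_voxel(self, affine3mm, rng):
        data = rng.standard_normal((6, 6, 6, 25))
        bold = Bold4D(data, affine3mm, 3.0)
        rmap = reho_map(bold, BrainMask.full((6, 6, 6), affine3mm), neighborhood=27)
        block = data[1:4, 2:5, 2:5].reshape(27, 25)  # neighbourhood of (2,3,3)
        assert rmap.values[2, 3, 3] == pytest.approx(kcc(block), abs=1e-10)


class TestStandardize:
    def _map(self, values, affine, flagged=None):
        from rehopipe.reho import RehoMap

        return RehoMap(
            values=values,
            mask=BrainMask.full(values.shape, affine),
            n_timepoints=20,
            neighborhood=27,
            flagged=flagged,
        )

    def test_uniform_half_becomes_one(self, affine3mm):
        out = standardize(self._map(np.full((4, 4, 4), 0.5), affine3mm))
        np.testing.assert_allclose(out.values, 1.0)
        assert out.standardized

    def test_mask_mean_is_exactly_one(self, affine3mm, rng):
        out = standardize(self._map(rng.random((5, 5, 5)) + 0.1, affine3mm))
        assert out.values[out.valid_mask].mean() == pytest.approx(1.0, rel=1e-10)

    def test_all_zero_map_is_an_error(self, affine3mm):
        with pytest.raises(ValueError, match="mean"):
            standardize(self._map(np.zeros((4, 4, 4)), affine3mm))

    def test_restandardization_is_idempotent(self, affine3mm, rng):
        once = standardize(self._map(rng.random((5, 5, 5)) + 0.1, affine3mm))
        twice = standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_flagged_voxels_excluded_from_mean(self, affine3mm):
        values = np.full((4, 4, 4), 2.0)
        flagged = np.zeros((4, 4, 4), dtype=bool)
        flagged[0, 0, 0] = True
        values[0, 0, 0] = 1000.0  # should not influence the mean
        out = standardize(self._map(values, affine3mm, flagged=flagged))
        assert out.values[1, 1, 1] == pytest.approx(1.0)
        assert out.values[0, 0, 0] == 0.0


class TestSmoothing:
    def _map(self, values, affine):
        from rehopipe.reho import RehoMap

        return RehoMap(
            values=values,
            mask=BrainMask.full(values.shape, affine),
            n_timepoints=20,
            neighborhood=27,
        )

    def test_zero_fwhm_is_identity(self, affine3mm, rng):
        values = rng.random((6, 6, 6))
        out = smooth_gaussian(self._map(values, affine3mm), 0.0)
        np.testing.assert_array_equal(out.values, values)

    def test_constant_map_unchanged(self, affine3mm):
        out = smooth_gaussian(self._map(np.full((8, 8, 8), 3.3), affine3mm), 6.0)
        np.testing.assert_allclose(out.values, 3.3, atol=1e-10)

    def test_impulse_response_matches_closed_form_gaussian(self, affine3mm):
        n = 31
        values = np.zeros((n, n, n))
        values[n // 2, n // 2, n // 2] = 1.0
        fwhm = 6.0
        out = smooth_gaussian(self._map(values, affine3mm), fwhm)
        sigma_vox = fwhm_to_sigma(fwhm) / 3.0  # 3 mm voxels
        x = np.arange(n) - n // 2
        g1 = np.exp(-(x**2) / (2 * sigma_vox**2))
        g1 /= g1.sum()
        expected = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        assert np.abs(out.values - expected).max() < 1e-6
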