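import numpy as np
import pytest
from scipy import ndimage, stats

from rehopipe.images import BrainMask
from rehopipe.glm import StatMap
from rehopipe.cluster import (
    alphasim_null,
    connectivity_structure,
    estimate_fwhm_mm,
    extent_threshold,
    label_clusters,
    report_clusters,
    MCNullDistribution,
)


def floodfill_labels(binary, connectivity):
    """Brute-force BFS connected components, pure Python."""
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                n_nonzero = sum(map(abs, (di, dj, dk)))
                if n_nonzero == 0:
                    continue
                if connectivity == 6 and n_nonzero > 1:
                    continue
                if connectivity == 18 and n_nonzero > 2:
                    continue
                offs.append((di, dj, dk))
    visited = np.zeros_like(binary, dtype=bool)
    comps = []
    shape = binary.shape
    for start in zip(*np.nonzero(binary)):
        if visited[start]:
            continue
        stack, comp = [start], set()
        visited[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for d in offs:
                w = tuple(a + b for a, b in zip(v, d))
                if all(0 <= w[i] < shape[i] for i in range(3)):
                    if binary[w] and not visited[w]:
                        visited[w] = True
                        stack.append(w)
        comps.append(frozenset(comp))
    return set(comps)


class TestLabeling:
    def test_single_voxel_is_one_cluster(self):
        m = np.zeros((5, 5, 5), dtype=int)
        m[2, 2, 2] = 1
        clusters = label_clusters(m, 6)
        assert len(clusters) == 1 and clusters[0].size == 1

    def test_corner_touch_depends_on_connectivity(self):
        m = np.zeros((4, 4, 4), dtype=int)
        m[0, 0, 0] = 1
        m[1, 1, 1] = 1  # shares only a corner
        assert len(label_clusters(m, 6)) == 2
        assert len(label_clusters(m, 26)) == 1

    def test_signs_are_labelled_separately(self):
        m = np.zeros((4, 4, 4), dtype=int)
        m[0, :2, 0] = 1
        m[0, 2:, 0] = -1  # adjacent but opposite sign
        clusters = label_clusters(m, 6)
        assert sorted((c.sign, c.size) for c in clusters) == [(-1, 2), (1, 2)]

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_bruteforce_floodfill(self, rng, connectivity):
        for _ in range(5):
            m = (rng.random((10, 10, 10)) < 0.25).astype(int)
            ours = {
                frozenset(map(tuple, c.voxels)) for c in label_clusters(m, connectivity)
            }
            assert ours == floodfill_labels(m > 0, connectivity)


class TestAlphaSimNull:
    def test_voxel_p_near_one_saturates_the_mask(self, affine3mm):
        # at voxel_p -> 1 every voxel is suprathreshold on one sign or the
        # other; signs cluster separately, so the maximum is the giant
        # same-sign component — far above anything a real threshold allows
        mask = BrainMask.full((8, 8, 8), affine3mm)
        null = alphasim_null(mask, voxel_p=1 - 1e-12, fwhm_mm=0, n_iterations=5, seed=1)
        assert (null.max_cluster_sizes > 0.4 * 8**3).all()
        big = alphasim_null(mask, voxel_p=1 - 1e-12, fwhm_mm=12.0, n_iterations=5, seed=1)
        assert (big.max_cluster_sizes > 0.4 * 8**3).all()

    def test_same_seed_reproduces_exactly(self, affine3mm):
        mask = BrainMask.full((10, 10, 10), affine3mm)
        a = alphasim_null(mask, n_iterations=50, seed=7)
        b = alphasim_null(mask, n_iterations=50, seed=7)
        np.testing.assert_array_equal(a.max_cluster_sizes, b.max_cluster_sizes)

    def test_unsmoothed_null_matches_direct_binomial_thinning(self, affine3mm, rng):
        # with FWHM 0 the field is iid noise: the max-cluster distribution
        # must match thresholding Bernoulli(p) maps directly
        p = 0.01
        mask = BrainMask.full((16, 16, 16), affine3mm)
        null = alphasim_null(mask, voxel_p=p, fwhm_mm=0, n_iterations=600, seed=3)
        structure = connectivity_structure(6)
        ref = []
        for _ in range(600):
            hot = rng.random((16, 16, 16)) < p / 2  # each tail keeps p/2
            cold = rng.random((16, 16, 16)) < p / 2
            best = 0
            for b in (hot, cold):
                labels, n = ndimage.label(b, structure=structure)
                if n:
                    best = max(best, int(np.bincount(labels.ravel())[1:].max()))
            ref.append(best)
        ks = stats.ks_2samp(null.max_cluster_sizes, ref)
        assert ks.pvalue > 0.01

    def test_empty_mask_rejected(self, affine3mm):
        with pytest.raises(ValueError, match="voxels"):
            BrainMask(np.zeros((4, 4, 4), dtype=bool), affine3mm)


class TestExtentThreshold:
    def _null(self, sizes):
        sizes = np.asarray(sizes)
        return MCNullDistribution(
            max_cluster_sizes=sizes,
            n_iterations=sizes.size,
            voxel_p=0.01,
            fwhm_mm=(6.0, 6.0, 6.0),
            connectivity=6,
            mask_id="test",
            seed=0,
        )

    def test_uniform_1_to_100_alpha_05_gives_96(self):
        assert extent_threshold(self._null(np.arange(1, 101)), 0.05) == 96

    def test_alpha_one_or_more_gives_one(self):
        assert extent_threshold(self._null(np.arange(1, 101)), 1.0) == 1

    def test_nonincreasing_in_alpha(self, rng):
        null = self._null(rng.integers(0, 50, 500))
        alphas = [0.001, 0.01, 0.05, 0.2, 0.5]
        ks = [extent_threshold(null, a) for a in alphas]
        assert ks == sorted(ks, reverse=True)

    def test_in_sample_fwe_at_most_alpha_by_construction(self, rng):
        null = self._null(rng.integers(0, 80, 1000))
        for alpha in (0.01, 0.05):
            k = extent_threshold(null, alpha)
            assert (null.max_cluster_sizes >= k).mean() <= alpha


class TestClusterReport:
    def _stat_with_blob(self, affine, df=84):
        t = np.zeros((20, 20, 20))
        blob = np.zeros_like(t, dtype=bool)
        # a 57-voxel blob: 3x4x4 box plus 9 extra voxels on one face
        blob[5:8, 5:9, 5:9] = True
        blob[8, 5:8, 5:8] = True
        assert blob.sum() == 57
        t[blob] = 3.5
        peak = (6, 6, 6)
        t[peak] = 3.88
        mask = BrainMask.full(t.shape, affine)
        return StatMap(t_values=t, df=df, contrast="g", mask=mask), blob, peak

    def test_planted_blob_reported_with_peak_and_world_coordinates(self, affine3mm):
        stat, blob, peak = self._stat_with_blob(affine3mm)
        report = report_clusters(stat, voxel_p=0.01, extent_k=35, connectivity=6)
        assert len(report.clusters) == 1
        c = report.clusters[0]
        assert c.size == 57
        assert c.peak_t == pytest.approx(3.88)
        assert c.peak_ijk == peak
        expected_xyz = (affine3mm @ np.array([*peak, 1.0]))[:3]
        assert c.peak_xyz_mm == pytest.approx(tuple(expected_xyz))

    def test_all_zero_map_gives_empty_report(self, affine3mm):
        stat = StatMap(
            t_values=np.zeros((6, 6, 6)),
            df=30,
            contrast="g",
            mask=BrainMask.full((6, 6, 6), affine3mm),
        )
        assert report_clusters(stat, 0.01, 10, 6).clusters == []

    def test_subthreshold_blob_excluded(self, affine3mm):
        stat, blob, _ = self._stat_with_blob(affine3mm)
        report = report_clusters(stat, voxel_p=0.01, extent_k=58, connectivity=6)
        assert report.clusters == []

    def test_peak_tie_broken_by_smallest_linear_index(self, affine3mm):
        t = np.zeros((8, 8, 8))
        t[2, 2, 2:5] = 4.0  # three tied peaks in one cluster
        stat = StatMap(
            t_values=t, df=30, contrast="g", mask=BrainMask.full(t.shape, affine3mm)
        )
        report = report_clusters(stat, 0.01, 1, 6)
        assert report.clusters[0].peak_ijk == (2, 2, 2)

    def test_report_round_trips_to_tsv(self, affine3mm, tmp_path):
        import pandas as pd

        stat, _, _ = self._stat_with_blob(affine3mm)
        report = report_clusters(stat, 0.01, 35, 6)
        path = report.save(tmp_path / "clusters.tsv")
        df = pd.read_csv(path, sep="\t", comment="#")
        assert list(df.columns) == [
            "sign", "size", "peak_t", "i", "j", "k", "x_mm", "y_mm", "z_mm", "label",
        ]
        assert df["size"].iloc[0] == 57


class TestSmoothnessEstimate:
    def test_recovers_applied_fwhm(self, affine3mm, rng):
        from scipy.ndimage import gaussian_filter

        fwhm = 6.0
        sigma_vox = fwhm / (2 * np.sqrt(2 * np.log(2))) / 3.0
        maps = np.stack(
            [gaussian_filter(rng.standard_normal((30, 30, 30)), sigma_vox) for _ in range(10)]
        )
        mask = BrainMask.full((30, 30, 30), affine3mm)
        est = estimate_fwhm_mm(maps, mask)
        assert np.allclose(est, fwhm, rtol=0.15)

    def test_white_noise_estimates_zero(self, affine3mm, rng):
        mask = BrainMask.full((20, 20, 20), affine3mm)
        est = estimate_fwhm_mm(rng.standard_normal((5, 20, 20, 20)), mask)
        assert max(est) < 2.0  # at or below the voxel scale
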