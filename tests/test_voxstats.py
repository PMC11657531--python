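"""Z-scoring, smoothing, permutation inference, FDR and cluster extraction."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from brainvox.core import BinaryMask, Volume
from brainvox.voxstats import (
    GroupDesign,
    StatMaps,
    balanced_assignments,
    extract_clusters,
    fdr_threshold,
    gaussian_smooth,
    permutation_ttest,
    zscore_volume,
)


def _vol(values, shape=None):
    arr = np.asarray(values, dtype=float)
    if shape is not None:
        arr = arr.reshape(shape)
    return Volume(arr, 25.0, "atlas")


def _mask(shape):
    return BinaryMask(np.ones(shape, np.uint8), 25.0, "atlas")


class TestZScore:
    def test_hand_computed_values(self):
        v = _vol([2.0, 4.0, 6.0, 99.0], (1, 2, 2))
        m = BinaryMask(np.array([1, 1, 1, 0], np.uint8).reshape(1, 2, 2), 25.0, "atlas")
        out = zscore_volume(v, m)
        sd = np.sqrt(8.0 / 3.0)
        np.testing.assert_allclose(
            out.data.ravel(), [-2 / sd, 0.0, 2 / sd, 0.0], atol=1e-12
        )
        assert out.data.ravel()[0] == pytest.approx(-1.2247448, abs=1e-6)

    def test_normalizes_to_zero_mean_unit_sd(self, rng):
        v = Volume(rng.normal(3, 7, (6, 6, 6)), 25.0, "atlas")
        m = BinaryMask((rng.random((6, 6, 6)) < 0.7).astype(np.uint8), 25.0, "atlas")
        out = zscore_volume(v, m)
        inside = m.astype_bool()
        assert out.data[inside].mean() == pytest.approx(0.0, abs=1e-9)
        assert out.data[inside].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert (out.data[~inside] == 0).all()

    def test_constant_image_rejected(self):
        v = _vol(np.full(8, 2.0), (2, 2, 2))
        with pytest.raises(ValueError):
            zscore_volume(v, _mask((2, 2, 2)))


class TestGaussianSmooth:
    def test_delta_matches_analytic_gaussian(self):
        n, sigma_vox = 33, 4.0
        data = np.zeros((n, n, n))
        data[16, 16, 16] = 1.0
        v = Volume(data, 25.0, "atlas")
        out = gaussian_smooth(v, kernel_um=sigma_vox * 25.0)
        zz, yy, xx = np.meshgrid(*([np.arange(n) - 16] * 3), indexing="ij")
        analytic = np.exp(-(zz**2 + yy**2 + xx**2) / (2 * sigma_vox**2))
        analytic /= (2 * np.pi * sigma_vox**2) ** 1.5
        core = (np.abs(zz) < 10) & (np.abs(yy) < 10) & (np.abs(xx) < 10)
        np.testing.assert_allclose(out.data[core], analytic[core], rtol=1e-3)
        assert np.unravel_index(out.data.argmax(), out.data.shape) == (16, 16, 16)

    def test_constant_image_unchanged(self):
        v = _vol(np.full(64, 3.7), (4, 4, 4))
        out = gaussian_smooth(v, 100.0)
        np.testing.assert_allclose(out.data, 3.7, atol=1e-9)

    def test_linearity(self, rng):
        x = Volume(rng.normal(size=(8, 8, 8)), 25.0, "atlas")
        y = Volume(rng.normal(size=(8, 8, 8)), 25.0, "atlas")
        lhs = gaussian_smooth(x.with_data(2 * x.data + 3 * y.data), 50.0).data
        rhs = 2 * gaussian_smooth(x, 50.0).data + 3 * gaussian_smooth(y, 50.0).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


def _brute_force_perm_p(values_a, values_b, contrast="two_sided"):
    """Enumerate every balanced relabeling with scipy's t-test."""
    pooled = list(values_a) + list(values_b)
    nA = len(values_a)
    t_obs = sps.ttest_ind(values_a, values_b, equal_var=True).statistic
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), nA):
        a = [pooled[i] for i in combo]
        b = [pooled[i] for i in range(len(pooled)) if i not in combo]
        t = sps.ttest_ind(a, b, equal_var=True).statistic
        total += 1
        if contrast == "two_sided":
            count += abs(t) >= abs(t_obs) - 1e-12
        elif contrast == "A>B":
            count += t >= t_obs - 1e-12
        else:
            count += t <= t_obs + 1e-12
    return count / total


class TestPermutationTTest:
    def _run(self, a_vals, b_vals, contrast="two_sided", n_perm=10_000, seed=0):
        subs = [f"s{i}" for i in range(len(a_vals) + len(b_vals))]
        groups = {s: ("A" if i < len(a_vals) else "B") for i, s in enumerate(subs)}
        stack = [_vol([v, v], (1, 1, 2)) for v in list(a_vals) + list(b_vals)]
        design = GroupDesign(subs, groups, contrast)
        return permutation_ttest(stack, design, _mask((1, 1, 2)), n_perm=n_perm, seed=seed)

    def test_scalar_example_three_vs_three(self):
        maps = self._run([1, 2, 3], [4, 5, 6])
        assert maps.exhaustive
        assert maps.n_permutations_used == 20
        assert maps.p_map[0, 0, 0] == pytest.approx(0.1)

    @pytest.mark.parametrize("contrast", ["two_sided", "A>B", "B>A"])
    def test_matches_enumeration_oracle(self, contrast, rng):
        a = rng.normal(0, 1, 4)
        b = rng.normal(1, 1, 4)
        maps = self._run(a, b, contrast)
        assert maps.exhaustive
        expected = _brute_force_perm_p(a, b, contrast)
        assert maps.p_map[0, 0, 0] == pytest.approx(expected)

    def test_label_swap_negates_t_keeps_p(self, rng):
        a = rng.normal(size=4)
        b = rng.normal(size=4)
        m1 = self._run(a, b)
        m2 = self._run(b, a)
        assert m1.t_map[0, 0, 0] == pytest.approx(-m2.t_map[0, 0, 0])
        assert m1.p_map[0, 0, 0] == pytest.approx(m2.p_map[0, 0, 0])

    def test_sampled_p_uses_add_one_estimator(self, rng):
        # 6+6 subjects: C(12,6)=924 > n_perm=99 -> Monte-Carlo path
        a = rng.normal(0, 1, 6)
        b = rng.normal(3, 1, 6)
        maps = self._run(a, b, n_perm=99)
        assert not maps.exhaustive
        assert maps.n_permutations_used == 99
        assert maps.p_map[0, 0, 0] >= 1 / 100

    def test_zero_variance_voxel_flagged_p_one(self):
        subs = [f"s{i}" for i in range(6)]
        groups = {s: ("A" if i < 3 else "B") for i, s in enumerate(subs)}
        stack = []
        for i, val in enumerate([1, 2, 3, 4, 5, 6]):
            stack.append(_vol([5.0, val], (1, 1, 2)))  # voxel 0 constant
        design = GroupDesign(subs, groups)
        maps = permutation_ttest(stack, design, _mask((1, 1, 2)), n_perm=100, seed=1)
        assert maps.p_map[0, 0, 0] == 1.0
        assert maps.zero_variance_mask[0, 0, 0]
        assert maps.p_map[0, 0, 1] < 1.0

    def test_observed_assignment_listed_first(self):
        labels = np.array([True, False, True, False])
        rows = balanced_assignments(labels)
        assert rows.shape == (6, 4)
        assert (rows[0] == labels).all()


class TestFDR:
    def _maps(self, pvals):
        shape = (1, 1, len(pvals))
        return StatMaps(
            t_map=np.zeros(shape),
            p_map=np.asarray(pvals, dtype=float).reshape(shape),
            analysis_mask=_mask(shape),
            n_permutations_used=100,
            exhaustive=False,
        )

    def test_hand_worked_step_up(self):
        sig, cutoff = fdr_threshold(self._maps([0.01, 0.02, 0.03, 0.5]), q=0.2)
        assert cutoff == pytest.approx(0.03)
        assert sig.n_voxels == 3

    def test_all_ones_gives_empty(self):
        sig, cutoff = fdr_threshold(self._maps([1.0, 1.0, 1.0]), q=0.2)
        assert cutoff == 0.0
        assert sig.n_voxels == 0

    def test_cutoff_monotone_in_q(self, rng):
        p = rng.random(200)
        maps = self._maps(p)
        cutoffs = [fdr_threshold(maps, q)[1] for q in (0.05, 0.1, 0.2, 0.4)]
        assert cutoffs == sorted(cutoffs)

    def test_bad_q_rejected(self):
        with pytest.raises(ValueError):
            fdr_threshold(self._maps([0.5]), q=1.5)


def _flood_fill_count(mask, neighbors):
    """Independent component counter: explicit stack-based flood fill."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    count = 0
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            pt = stack.pop()
            for off in neighbors:
                nb = tuple(p + o for p, o in zip(pt, off))
                if all(0 <= n < s for n, s in zip(nb, mask.shape)) and mask[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
    return count


N26 = [
    (i, j, k)
    for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


class TestExtractClusters:
    def test_extent_threshold_filters_small_blob(self):
        sig = np.zeros((20, 20, 20), np.uint8)
        sig[1:9, 1:9, 1:9] = 1        # 512 voxels
        sig[12:17, 12:17, 12:17] = 1  # 125 voxels
        t = np.ones((20, 20, 20))
        cm = extract_clusters(BinaryMask(sig, 25.0, "atlas"), t, min_voxels=400)
        assert list(cm.table["n_voxels"]) == [512]
        assert cm.table.iloc[0]["sign"] == 1

    def test_min_one_matches_flood_fill_oracle(self, rng):
        sig = (rng.random((16, 16, 16)) < 0.2).astype(np.uint8)
        t = np.ones(sig.shape)
        cm = extract_clusters(BinaryMask(sig, 25.0, "atlas"), t, min_voxels=1, connectivity=26)
        assert len(cm.table) == _flood_fill_count(sig, N26)

    def test_corner_touching_blobs_depend_on_connectivity(self):
        sig = np.zeros((6, 6, 6), np.uint8)
        sig[1, 1, 1] = 1
        sig[2, 2, 2] = 1
        t = np.ones(sig.shape)
        m6 = extract_clusters(BinaryMask(sig, 25.0, "atlas"), t, 1, connectivity=6)
        m26 = extract_clusters(BinaryMask(sig, 25.0, "atlas"), t, 1, connectivity=26)
        assert len(m6.table) == 2
        assert len(m26.table) == 1

    def test_opposite_sign_regions_never_merge(self):
        sig = np.zeros((8, 8, 8), np.uint8)
        sig[2:6, 2:6, 2:4] = 1
        sig[2:6, 2:6, 4:6] = 1
        t = np.ones((8, 8, 8))
        t[..., 4:] = -1.0
        cm = extract_clusters(BinaryMask(sig, 25.0, "atlas"), t, min_voxels=1)
        assert len(cm.table) == 2
        assert sorted(cm.table["sign"]) == [-1, 1]

    def test_labels_ordered_by_descending_size(self, rng):
        sig = (rng.random((16, 16, 16)) < 0.15).astype(np.uint8)
        t = rng.normal(size=sig.shape)
        cm = extract_clusters(BinaryMask(sig, 25.0, "atlas"), t, min_voxels=1)
        sizes = list(cm.table["n_voxels"])
        assert sizes == sorted(sizes, reverse=True)
        for cid, size in zip(cm.table["cluster_id"], sizes):
            assert (cm.labels == cid).sum() == size

    def test_empty_input_gives_empty_map(self):
        cm = extract_clusters(
            BinaryMask(np.zeros((4, 4, 4), np.uint8), 25.0, "atlas"),
            np.zeros((4, 4, 4)), min_voxels=1,
        )
        assert len(cm.table) == 0
        assert (cm.labels == 0).all()
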