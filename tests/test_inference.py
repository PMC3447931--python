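import numpy as np
import pytest
from scipy import stats

from alffkit.inference import (
    GroupDesign,
    InferenceConfig,
    ancova_image_covariate,
    ancova_scalar_covariate,
    chi_square_2x2,
    critical_t,
    extract_clusters,
    permutation_cluster_fwe,
    t_test_from_summary,
    two_sample_tmap,
)
from alffkit.types import BrainMask, InputError, ScalarMap

from conftest import random_maps


def make_design(na, nb, **kw):
    ids = [f"s{i}" for i in range(na + nb)]
    return GroupDesign(ids, ["patient"] * na + ["control"] * nb, **kw)


# ---------------------------------------------------------------------------
# scalar statistics

class TestTTestFromSummary:
    def test_table1_age_comparison(self):
        # printed summary stats: 45.30 +/- 9.95 vs 47.05 +/- 9.89, n=20 each
        _, p = t_test_from_summary(45.30, 9.95, 20, 47.05, 9.89, 20)
        assert round(p, 2) == 0.58

    def test_equal_groups(self):
        t, p = t_test_from_summary(5.0, 2.0, 10, 5.0, 2.0, 10)
        assert t == 0.0
        assert p == 1.0

    def test_closed_form_t(self):
        t, _ = t_test_from_summary(0.0, 1.0, 10, 1.0, 1.0, 10)
        assert abs(t - (-2.2361)) < 1e-3

    def test_degenerate_zero_sd(self):
        assert t_test_from_summary(1.0, 0.0, 5, 1.0, 0.0, 5) == (0.0, 1.0)


class TestChiSquare:
    def test_table1_sex_comparison(self):
        stat, p = chi_square_2x2(13, 7, 14, 6)
        assert round(p, 2) == 0.74
        assert abs(stat - 0.1140) < 1e-3

    def test_balanced_table(self):
        stat, p = chi_square_2x2(10, 10, 10, 10)
        assert stat == 0.0
        assert p == 1.0

    def test_zero_margin_errors(self):
        with pytest.raises(InputError):
            chi_square_2x2(0, 0, 5, 5)


class TestCriticalT:
    def test_paper_threshold(self):
        assert round(critical_t(0.001, 38, "one"), 2) == 3.32

    def test_median(self):
        assert abs(critical_t(0.5, 7, "one")) < 1e-12

    def test_normal_limit(self):
        assert abs(critical_t(0.025, 1_000_000, "one") - 1.96) < 0.01

    def test_two_tailed(self):
        assert abs(critical_t(0.05, 30, "two") - stats.t.isf(0.025, 30)) < 1e-12


# ---------------------------------------------------------------------------
# t-maps

class TestTwoSampleTmap:
    def test_identical_groups_zero(self, rng, full_mask):
        maps = random_maps(rng, 3)
        t = two_sample_tmap(maps, [ScalarMap(m.data.copy(), m.affine) for m in maps],
                            full_mask)
        np.testing.assert_array_equal(t.data, 0.0)
        assert t.df == 4

    def test_single_voxel_toy(self, eye_affine):
        mask = BrainMask(np.ones((1, 1, 1), bool), eye_affine)
        a = [ScalarMap(np.full((1, 1, 1), v), eye_affine) for v in (1.0, 2.0, 3.0)]
        b = [ScalarMap(np.full((1, 1, 1), v), eye_affine) for v in (1.0, 2.0, 3.0)]
        assert two_sample_tmap(a, b, mask).data[0, 0, 0] == 0.0

    def test_matches_per_voxel_oracle(self, rng, full_mask):
        ga, gb = random_maps(rng, 5), random_maps(rng, 5)
        tmap = two_sample_tmap(ga, gb, full_mask)
        A = np.stack([m.data for m in ga])
        B = np.stack([m.data for m in gb])
        for idx in np.ndindex(4, 4, 4):
            t_ref, _ = stats.ttest_ind(A[(slice(None), *idx)], B[(slice(None), *idx)])
            assert abs(tmap.data[idx] - t_ref) < 1e-10

    def test_sign_antisymmetry(self, rng, full_mask):
        ga, gb = random_maps(rng, 4), random_maps(rng, 6)
        t1 = two_sample_tmap(ga, gb, full_mask)
        t2 = two_sample_tmap(gb, ga, full_mask)
        np.testing.assert_array_equal(t1.data, -t2.data)

    def test_too_few_maps_errors(self, rng, full_mask):
        with pytest.raises(InputError):
            two_sample_tmap(random_maps(rng, 1), random_maps(rng, 3), full_mask)


# ---------------------------------------------------------------------------
# clusters

def flood_fill_oracle(binary, offsets):
    """Brute-force connected components with explicit neighbor offsets."""
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(binary)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            vox = stack.pop()
            for off in offsets:
                nb = tuple(np.add(vox, off))
                if any(c < 0 or c >= s for c, s in zip(nb, binary.shape)):
                    continue
                if binary[nb] and not labels[nb]:
                    labels[nb] = current
                    stack.append(nb)
    return labels, current


def offsets_for(connectivity):
    offs = []
    for off in np.ndindex(3, 3, 3):
        d = np.array(off) - 1
        order = int(np.abs(d).sum())
        if order == 0:
            continue
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offs.append(tuple(d))
    return offs


class TestExtractClusters:
    def test_all_zero_map_empty(self, eye_affine):
        t = ScalarMap(np.zeros((5, 5, 5)), eye_affine, kind="tstat", df=10)
        assert len(extract_clusters(t, 3.32)) == 0

    def test_block_cluster(self, eye_affine):
        data = np.zeros((7, 7, 7))
        data[2:5, 2:5, 2:5] = 5.0
        t = ScalarMap(data, eye_affine, kind="tstat", df=10)
        table = extract_clusters(t, 3.32)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.n_voxels == 27
        assert row.peak_t == 5.0
        assert row.sign == 1

    @pytest.mark.parametrize("offset,expected", [
        # edge-sharing diagonal pair: one cluster at 18/26, two at 6
        ((1, 1, 0), {6: 2, 18: 1, 26: 1}),
        # corner-sharing diagonal pair: one cluster only at 26
        ((1, 1, 1), {6: 2, 18: 2, 26: 1}),
    ])
    def test_diagonal_connectivity(self, eye_affine, offset, expected):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 5.0
        data[2 + offset[0], 2 + offset[1], 2 + offset[2]] = 5.0
        t = ScalarMap(data, eye_affine, kind="tstat", df=10)
        for conn, n_expected in expected.items():
            assert len(extract_clusters(t, 3.32, connectivity=conn)) == n_expected

    @pytest.mark.parametrize("conn", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, rng, eye_affine, conn):
        data = rng.normal(scale=3.0, size=(6, 6, 6))
        t = ScalarMap(data, eye_affine, kind="tstat", df=10)
        table = extract_clusters(t, 3.32, connectivity=conn, tail="positive")
        _, n_oracle = flood_fill_oracle(data > 3.32, offsets_for(conn))
        assert len(table) == n_oracle
        # partition: cluster sizes sum to the suprathreshold voxel count
        assert table["n_voxels"].sum() == int((data > 3.32).sum())

    def test_negative_tail(self, eye_affine):
        data = np.zeros((5, 5, 5))
        data[1, 1, 1] = -6.0
        t = ScalarMap(data, eye_affine, kind="tstat", df=10)
        table = extract_clusters(t, 3.32, tail="both")
        assert len(table) == 1
        assert table.iloc[0].sign == -1
        assert table.iloc[0].peak_t == -6.0
        assert len(extract_clusters(t, 3.32, tail="positive")) == 0

    def test_peak_world_coordinate(self):
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-4, -4, -4]
        data = np.zeros((5, 5, 5))
        data[3, 4, 1] = 9.0
        t = ScalarMap(data, affine, kind="tstat", df=10)
        row = extract_clusters(t, 3.32).iloc[0]
        assert (row.peak_x_mm, row.peak_y_mm, row.peak_z_mm) == (2.0, 4.0, -2.0)


# ---------------------------------------------------------------------------
# permutation FWE

class TestPermutationFWE:
    def test_p_bounded_below(self, rng, full_mask):
        maps = random_maps(rng, 10)
        maps[0].data[0, 0, 0] += 50  # force a cluster
        design = make_design(5, 5)
        cfg = InferenceConfig(cluster_forming_t=2.0, n_permutations=100, seed=0)
        table = permutation_cluster_fwe(maps, design, full_mask, cfg)
        assert len(table) > 0
        assert (table["p_corrected"] >= 1.0 / 252).all()  # C(10,5)=252

    def test_exhaustive_when_feasible(self, rng, full_mask):
        # C(6,3)=20 <= 100 permutations: exhaustive enumeration, deterministic
        maps = random_maps(rng, 6)
        design = make_design(3, 3)
        cfg = InferenceConfig(cluster_forming_t=1.5, n_permutations=100, seed=1)
        t1 = permutation_cluster_fwe(maps, design, full_mask, cfg)
        cfg2 = InferenceConfig(cluster_forming_t=1.5, n_permutations=100, seed=99)
        t2 = permutation_cluster_fwe(maps, design, full_mask, cfg2)
        # exhaustive null does not depend on the seed
        if len(t1):
            np.testing.assert_array_equal(t1["p_corrected"], t2["p_corrected"])
            assert (t1["p_corrected"] >= 1.0 / 20).all()

    def test_deterministic_given_seed(self, rng, full_mask):
        maps = random_maps(rng, 12)
        design = make_design(6, 6)
        cfg = InferenceConfig(cluster_forming_t=1.5, n_permutations=150, seed=42)
        t1 = permutation_cluster_fwe(maps, design, full_mask, cfg)
        t2 = permutation_cluster_fwe(maps, design, full_mask, cfg)
        if len(t1):
            np.testing.assert_array_equal(t1["p_corrected"], t2["p_corrected"])

    def test_planted_effect_detected(self, eye_affine):
        g = np.random.default_rng(5)
        shape = (6, 6, 6)
        mask = BrainMask(np.ones(shape, bool), eye_affine)
        roi = np.zeros(shape, bool)
        roi[2:4, 2:4, 2:4] = True
        maps = []
        for i in range(16):
            data = g.normal(size=shape) * 0.1 + 1.0
            if i < 8:
                data[roi] += 2.0
            maps.append(ScalarMap(data, eye_affine))
        design = make_design(8, 8)
        cfg = InferenceConfig(cluster_forming_t=3.0, n_permutations=200, seed=3)
        table = permutation_cluster_fwe(maps, design, mask, cfg)
        sig = table[(table["p_corrected"] < 0.05) & (table["sign"] == 1)]
        assert len(sig) == 1
        # cluster contains the planted ROI, possibly plus a noise fringe
        row = sig.iloc[0]
        assert roi.sum() <= row.n_voxels <= roi.sum() + 3
        assert roi[int(row.peak_i), int(row.peak_j), int(row.peak_k)]


# ---------------------------------------------------------------------------
# covariate models

def regression_t_oracle(y, X, coef=1):
    """Independent normal-equations solve with explicit se computation."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = (resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta[coef] / np.sqrt(cov[coef, coef])


class TestAncovaImageCovariate:
    def test_zero_covariate_reduces_to_two_sample(self, rng, full_mask):
        maps = random_maps(rng, 10)
        zeros = [ScalarMap(np.zeros((4, 4, 4)), np.eye(4), kind="gm_prob")
                 for _ in range(10)]
        design = make_design(5, 5, image_covariates=zeros)
        t_adj = ancova_image_covariate(maps, design, full_mask)
        t_plain = two_sample_tmap(maps[:5], maps[5:], full_mask)
        np.testing.assert_allclose(t_adj.data, t_plain.data, atol=1e-10)

    def test_covariate_equal_to_response_gives_zero(self, rng, full_mask):
        maps = random_maps(rng, 8)
        covs = [ScalarMap(m.data.copy(), m.affine, kind="gm_prob") for m in maps]
        design = make_design(4, 4, image_covariates=covs)
        t = ancova_image_covariate(maps, design, full_mask)
        np.testing.assert_allclose(t.data, 0.0, atol=1e-8)

    def test_matches_regression_oracle(self, rng, full_mask):
        maps = random_maps(rng, 10)
        covs = random_maps(rng, 10, kind="gm_prob")
        design = make_design(5, 5, image_covariates=covs)
        t = ancova_image_covariate(maps, design, full_mask)
        assert t.df == 7
        Y = np.stack([m.data for m in maps])
        G = np.stack([c.data for c in covs])
        grp = np.array([1.0] * 5 + [0.0] * 5)
        for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3), (2, 0, 1)]:
            X = np.stack([np.ones(10), grp, G[(slice(None), *idx)]], axis=1)
            t_ref = regression_t_oracle(Y[(slice(None), *idx)], X)
            assert abs(t.data[idx] - t_ref) < 1e-8

    def test_missing_covariates_error(self, rng, full_mask):
        maps = random_maps(rng, 6)
        design = make_design(3, 3)
        with pytest.raises(InputError):
            ancova_image_covariate(maps, design, full_mask)


class TestAncovaScalarCovariate:
    def test_constant_covariate_drops_to_two_sample(self, rng, full_mask):
        maps = random_maps(rng, 10)
        design = make_design(5, 5, scalar_covariates={"tiv": np.full(10, 1500.0)})
        t_adj = ancova_scalar_covariate(maps, design, "tiv", full_mask)
        t_plain = two_sample_tmap(maps[:5], maps[5:], full_mask)
        np.testing.assert_allclose(t_adj.data, t_plain.data, atol=1e-10)
        assert t_adj.df == 8

    def test_matches_regression_oracle(self, rng, full_mask):
        maps = random_maps(rng, 10)
        tiv = rng.normal(1500, 100, size=10)
        design = make_design(5, 5, scalar_covariates={"tiv": tiv})
        t = ancova_scalar_covariate(maps, design, "tiv", full_mask)
        assert t.df == 7
        Y = np.stack([m.data for m in maps])
        grp = np.array([1.0] * 5 + [0.0] * 5)
        X = np.stack([np.ones(10), grp, tiv], axis=1)
        for idx in [(0, 0, 0), (2, 3, 1), (3, 3, 3)]:
            t_ref = regression_t_oracle(Y[(slice(None), *idx)], X)
            assert abs(t.data[idx] - t_ref) < 1e-8

    def test_identical_groups_zero(self, rng, full_mask):
        maps5 = random_maps(rng, 5)
        maps = maps5 + [ScalarMap(m.data.copy(), m.affine) for m in maps5]
        tiv = np.concatenate([np.arange(5.0), np.arange(5.0)]) + 100
        design = make_design(5, 5, scalar_covariates={"tiv": tiv})
        t = ancova_scalar_covariate(maps, design, "tiv", full_mask)
        np.testing.assert_allclose(t.data, 0.0, atol=1e-10)

    def test_unknown_covariate_errors(self, rng, full_mask):
        maps = random_maps(rng, 6)
        design = make_design(3, 3)
        with pytest.raises(InputError):
            ancova_scalar_covariate(maps, design, "tiv", full_mask)


class TestGroupDesign:
    def test_rejects_single_subject_group(self):
        with pytest.raises(InputError):
            GroupDesign(["a", "b", "c"], ["patient", "control", "control"])

    def test_rejects_unknown_labels(self):
        with pytest.raises(InputError):
            GroupDesign(["a", "b", "c", "d"], ["p", "p", "c", "c"])
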