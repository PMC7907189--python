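import numpy as np
import pytest
from scipy import stats

import lesionmap as lm
from lesionmap.core_volumes import VolumeGrid
from lesionmap.errors import CoverageError, DataError, DesignError
from lesionmap.normative_connectome import (
    ConnectivityMap,
    _logistic_wald,
    fdr_correct,
    laterality_contrast,
    pearson_map,
    rmap,
    seed_timeseries,
)

from conftest import make_mask


def bruteforce_bh(p, q):
    """O(m^2) step-up oracle: for each i check the step-up condition directly."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestSeedTimeseries:
    def test_single_voxel_seed_is_identity(self):
        rng = np.random.default_rng(0)
        bold = rng.normal(size=(3, 3, 3, 10))
        seed = np.zeros((3, 3, 3), dtype=bool)
        seed[1, 2, 0] = True
        np.testing.assert_array_equal(seed_timeseries(seed, bold), bold[1, 2, 0])

    def test_two_voxel_seed_is_their_mean(self):
        rng = np.random.default_rng(1)
        bold = rng.normal(size=(2, 2, 2, 7))
        seed = np.zeros((2, 2, 2), dtype=bool)
        seed[0, 0, 0] = seed[1, 1, 1] = True
        np.testing.assert_allclose(
            seed_timeseries(seed, bold), (bold[0, 0, 0] + bold[1, 1, 1]) / 2
        )

    def test_seed_outside_field_of_view_rejected(self):
        bold = np.zeros((2, 2, 2, 5))
        with pytest.raises(CoverageError):
            seed_timeseries(np.zeros((3, 3, 3), dtype=bool), bold)

    def test_constant_seed_series_gives_undefined_r(self):
        bold = np.zeros((2, 2, 2, 6))
        bold[1, 1, 1] = np.arange(6)
        seed = np.zeros((2, 2, 2), dtype=bool)
        seed[0, 0, 0] = True  # constant zero series
        series = seed_timeseries(seed, bold)
        r = pearson_map(series, bold)
        assert np.isnan(r).all()


class TestRmap:
    def test_hand_sized_case_matches_bruteforce_pearson(self):
        rng = np.random.default_rng(7)
        bold = rng.normal(size=(3, 1, 1, 5))
        seed = np.zeros((3, 1, 1), dtype=np.uint8)
        seed[0] = 1
        m = make_mask(seed)
        cm = rmap(m, [bold], mask_seed_voxels=False)
        for v in (1, 2):
            expected = np.corrcoef(bold[0, 0, 0], bold[v, 0, 0])[0, 1]
            assert cm.grid.data[v, 0, 0] == pytest.approx(expected, abs=1e-10)
        # the seed voxel's self-correlation is clipped before Fisher z
        assert cm.grid.data[0, 0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_multi_subject_aggregation_is_mean_fisher_z(self):
        rng = np.random.default_rng(8)
        bolds = [rng.normal(size=(4, 2, 2, 30)) for _ in range(3)]
        seed = np.zeros((4, 2, 2), dtype=np.uint8)
        seed[0, 0, 0] = 1
        cm = rmap(make_mask(seed), bolds, mask_seed_voxels=False)
        v = (2, 1, 1)
        zs = [
            np.arctanh(np.corrcoef(b[0, 0, 0], b[v])[0, 1]) for b in bolds
        ]
        assert cm.grid.data[v] == pytest.approx(np.tanh(np.mean(zs)), abs=1e-10)

    def test_voxel_equal_to_seed_series_gives_r_one(self):
        rng = np.random.default_rng(9)
        bold = rng.normal(size=(3, 1, 1, 20))
        bold[1, 0, 0] = bold[0, 0, 0]
        seed = np.zeros((3, 1, 1), dtype=np.uint8)
        seed[0] = 1
        cm = rmap(make_mask(seed), [bold], mask_seed_voxels=False)
        assert cm.grid.data[1, 0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_r_small_and_symmetric(self):
        rng = np.random.default_rng(10)
        bolds = [rng.normal(size=(10, 10, 10, 60)) for _ in range(4)]
        seed = np.zeros((10, 10, 10), dtype=np.uint8)
        seed[0, 0, :3] = 1
        cm = rmap(make_mask(seed), bolds)
        vals = cm.grid.data[np.isfinite(cm.grid.data)]
        assert abs(np.mean(vals)) < 0.02
        assert np.mean(np.abs(vals)) < 0.1

    def test_seed_voxels_flagged_nan(self):
        rng = np.random.default_rng(11)
        bold = rng.normal(size=(3, 3, 3, 15))
        seed = np.zeros((3, 3, 3), dtype=np.uint8)
        seed[1, 1, 1] = 1
        cm = rmap(make_mask(seed), [bold])
        assert np.isnan(cm.grid.data[1, 1, 1])

    def test_empty_normative_dataset_rejected(self, tmp_path):
        seed = np.zeros((2, 2, 2), dtype=np.uint8)
        seed[0, 0, 0] = 1
        with pytest.raises(DataError):
            rmap(make_mask(seed), tmp_path)


class TestFdrCorrect:
    def test_hand_step_up_example(self):
        # thresholds 0.0125 / 0.025 / 0.0375 / 0.05 -> first three rejected
        reject = fdr_correct([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert reject.tolist() == [True, True, True, False]

    def test_all_ones_give_no_rejections(self):
        assert not fdr_correct(np.ones(50), q=0.05).any()

    def test_matches_quadratic_oracle_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            m = int(rng.integers(1, 40))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            q = rng.uniform(0.01, 0.2)
            np.testing.assert_array_equal(fdr_correct(p, q), bruteforce_bh(p, q))

    def test_rejections_monotone_in_q(self):
        rng = np.random.default_rng(1)
        p = rng.random(200) ** 2
        counts = [fdr_correct(p, q).sum() for q in (0.01, 0.05, 0.1, 0.2)]
        assert counts == sorted(counts)


class TestLogisticFit:
    def test_matches_statsmodels_on_converging_data(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        y = (rng.random(40) < 0.5).astype(float)
        X = rng.normal(size=(40, 5)) + 0.8 * y[:, None]
        wald, lr_p, b1, conv, sep = _logistic_wald(y, X)
        for v in range(5):
            xs = (X[:, v] - X[:, v].mean()) / X[:, v].std()
            fit = sm.Logit(y, sm.add_constant(xs)).fit(disp=0)
            assert b1[v] == pytest.approx(fit.params[1], rel=1e-6)
            assert wald[v] == pytest.approx(fit.params[1] / fit.bse[1], rel=1e-5)
            assert lr_p[v] == pytest.approx(fit.llr_pvalue, rel=1e-6)

    def test_complete_separation_flagged(self):
        y = np.array([0.0] * 5 + [1.0] * 5)
        x = np.arange(10.0)[:, None]
        _, _, _, _, sep = _logistic_wald(y, x)
        assert sep[0]

    def test_zero_variance_covariate_flagged(self):
        y = np.array([0.0, 1.0] * 5)
        x = np.ones((10, 1))
        _, _, _, _, sep = _logistic_wald(y, x)
        assert sep[0]


class TestLateralityContrast:
    def _toy_maps(self, rng, n_left=5, n_right=5, shape=(4, 4, 4), shift=0.0):
        grid = VolumeGrid(np.zeros(shape))
        maps = []
        for i in range(n_left + n_right):
            lat = "right" if i >= n_left else "left"
            r = np.tanh(rng.normal(0, 0.2, size=shape) + (shift if lat == "right" else 0))
            maps.append(ConnectivityMap(grid.like(r), f"s{i}", lat))
        return maps

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        maps = self._toy_maps(rng, n_left=6, n_right=0)
        with pytest.raises(DesignError):
            laterality_contrast(maps, labels=["left"] * 6)

    def test_constant_voxel_flagged_undefined(self):
        rng = np.random.default_rng(1)
        maps = self._toy_maps(rng)
        for m in maps:
            m.grid.data[0, 0, 0] = 0.5
        contrast = laterality_contrast(maps)
        assert np.isnan(contrast.stat_map.data[0, 0, 0])
        assert contrast.diagnostics["undefined_voxels"] >= 1

    def test_relabeling_flips_sign_of_statistic(self):
        rng = np.random.default_rng(2)
        maps = self._toy_maps(rng, shift=0.3)
        labels = [m.laterality for m in maps]
        flipped = ["left" if l == "right" else "right" for l in labels]
        c1 = laterality_contrast(maps, labels=labels)
        c2 = laterality_contrast(maps, labels=flipped)
        a, b = c1.stat_map.data, c2.stat_map.data
        both = np.isfinite(a) & np.isfinite(b)
        np.testing.assert_allclose(a[both], -b[both], atol=1e-6)
        np.testing.assert_array_equal(c1.fdr_mask.data[both], c2.fdr_mask.data[both])

    def test_positive_statistic_means_right_greater(self):
        rng = np.random.default_rng(3)
        maps = self._toy_maps(rng, n_left=8, n_right=8, shift=0.5)
        c = laterality_contrast(maps)
        stat = c.stat_map.data[np.isfinite(c.stat_map.data)]
        assert np.median(stat) > 0

    def test_ranksum_alternative_agrees_on_direction(self, default_rmaps, default_connectome):
        # the Wald magnitude saturates for strong effects, so only the sign
        # is comparable between the logistic and rank-sum statistics
        c_log = laterality_contrast(default_rmaps, q=0.01, method="logistic")
        c_rs = laterality_contrast(default_rmaps, q=0.01, method="ranksum")
        RT = default_connectome.layout.right_targets
        s1, s2 = c_log.stat_map.data[RT], c_rs.stat_map.data[RT]
        both = np.isfinite(s1) & np.isfinite(s2)
        agree = np.mean(np.sign(s1[both]) == np.sign(s2[both]))
        assert agree > 0.9

    def test_planted_right_network_dominates_significance(
        self, default_rmaps, default_connectome
    ):
        conn = default_connectome
        c = laterality_contrast(default_rmaps, q=0.01)
        fdr = np.asarray(c.fdr_mask.data, bool)
        n_right = int((fdr & conn.layout.right_targets).sum())
        n_left = int((fdr & conn.layout.left_targets).sum())
        assert n_right > n_left
        assert n_right > 0.5 * conn.layout.right_targets.sum()
        # significant right-target voxels should carry positive statistics
        stat = c.stat_map.data[fdr & conn.layout.right_targets]
        assert np.nanmedian(stat) > 0
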