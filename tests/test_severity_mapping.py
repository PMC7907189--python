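import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import lesionmap as lm
from lesionmap.core_volumes import SubjectRecord
from lesionmap.errors import AlignmentError, ValidationError
from lesionmap.severity_mapping import (
    build_average_map,
    build_frequency_map,
    build_severity_mapset,
    engel_ccsfs_association,
    frequency_mask,
    frequency_threshold,
    map_centroid,
    significant_fraction,
    signed_rank_p,
    signed_rank_p_bruteforce,
    voxelwise_wilcoxon,
)

from conftest import make_mask


def block_mask(shape, sl, **kwargs):
    data = np.zeros(shape, dtype=np.uint8)
    data[sl] = 1
    return make_mask(data, **kwargs)


class TestFrequencyMap:
    def test_single_mask_equals_itself(self):
        m = block_mask((4, 4, 4), np.s_[1:3])
        freq = build_frequency_map([m])
        assert np.array_equal(freq.data, m.grid.data)

    def test_duplicated_mask_counts_twice(self):
        m = block_mask((4, 4, 4), np.s_[1:3])
        freq = build_frequency_map([m, m])
        assert set(np.unique(freq.data)) == {0, 2}

    def test_counting_identity(self):
        rng = np.random.default_rng(2)
        masks = [
            block_mask((5, 5, 5), np.s_[i : i + 2]) for i in range(3)
        ]
        freq = build_frequency_map(masks)
        assert freq.data.sum() == sum(m.n_voxels for m in masks)

    def test_misaligned_masks_rejected(self):
        a = block_mask((4, 4, 4), np.s_[:2])
        b = block_mask((4, 4, 4), np.s_[:2], spacing=(2, 2, 2))
        with pytest.raises(AlignmentError):
            build_frequency_map([a, b])


class TestFrequencyMask:
    @pytest.mark.parametrize(
        "n,fraction,expected", [(35, 0.10, 4), (35, 0.0, 1), (35, 1.0, 35), (10, 0.10, 1)]
    )
    def test_threshold_is_ceiling_of_fraction(self, n, fraction, expected):
        assert frequency_threshold(n, fraction) == expected

    def test_fraction_one_keeps_only_full_overlap(self):
        a = block_mask((4, 4, 4), np.s_[0:2])
        b = block_mask((4, 4, 4), np.s_[1:3])
        freq = build_frequency_map([a, b])
        fm = frequency_mask(freq, 2, fraction=1.0)
        assert np.array_equal(fm.data > 0, np.asarray(freq.data) == 2)


class TestAverageMap:
    def test_equal_size_masks_average_scores(self):
        a = block_mask((4, 4, 4), np.s_[0:2], score=2)
        b = block_mask((4, 4, 4), np.s_[1:3], score=4)
        avg = build_average_map([a, b])
        assert avg.data[1, 0, 0] == pytest.approx(3.0)  # overlap voxel
        assert avg.data[0, 0, 0] == pytest.approx(2.0)  # only mask a

    def test_size_normalized_weighted_mean_hand_value(self):
        # masks of 10 and 40 voxels, scores 0 and 4, overlapping at one voxel:
        # (0.1*0 + 0.025*4) / (0.1 + 0.025) = 0.8
        shape = (50, 1, 1)
        a = block_mask(shape, np.s_[0:10], score=0)
        b = block_mask(shape, np.s_[9:49], score=4)
        avg = build_average_map([a, b])
        assert avg.data[9, 0, 0] == pytest.approx(0.8)

    def test_single_mask_map_equals_its_score(self):
        m = block_mask((3, 3, 3), np.s_[1:2], score=3)
        avg = build_average_map([m])
        assert np.nanmax(avg.data) == np.nanmin(avg.data[m.indicator]) == 3.0

    def test_values_bounded_by_contributing_scores(self):
        rng = np.random.default_rng(5)
        masks = [
            block_mask((6, 6, 6), np.s_[i : i + 3], score=int(rng.integers(0, 5)))
            for i in range(4)
        ]
        avg = build_average_map(masks)
        vals = avg.data[np.isfinite(avg.data)]
        scores = [m.score for m in masks]
        assert vals.min() >= min(scores) and vals.max() <= max(scores)

    def test_equal_sizes_make_normalization_a_noop(self):
        masks = [
            block_mask((4, 4, 4), np.s_[i : i + 2], score=s)
            for i, s in [(0, 1), (1, 4), (2, 2)]
        ]
        a = build_average_map(masks, size_normalize=True)
        b = build_average_map(masks, size_normalize=False)
        np.testing.assert_allclose(a.data, b.data)

    def test_score_out_of_range_rejected(self):
        m = block_mask((3, 3, 3), np.s_[0:1])
        with pytest.raises(ValidationError):
            build_average_map([m], scores=[7])


class TestSignedRankP:
    def test_all_differences_zero_gives_one(self):
        p, degenerate = signed_rank_p([0.0, 0.0, 0.0])
        assert p == 1.0 and degenerate

    def test_one_sided_extreme_sample(self):
        # five equal scores all below the reference: W+ = 0, p = 2/32
        p, _ = signed_rank_p([-2.5] * 5)
        assert p == pytest.approx(2 / 32)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_exact_p_equals_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        diffs = rng.choice([-2.1, -1.1, -0.1, 0.9, 1.9, 0.0], size=n)
        p, _ = signed_rank_p(diffs)
        assert p == pytest.approx(signed_rank_p_bruteforce(diffs), abs=1e-12)

    def test_exact_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            d = rng.normal(size=int(rng.integers(5, 15)))
            p, _ = signed_rank_p(d)
            assert p == pytest.approx(stats.wilcoxon(d, method="exact").pvalue, abs=1e-12)

    def test_approx_matches_scipy_pratt(self):
        rng = np.random.default_rng(9)
        d = np.round(rng.normal(size=40), 1)  # ties and zeros likely
        p, _ = signed_rank_p(d, exact_max_n=25)
        ref = stats.wilcoxon(
            d, zero_method="pratt", correction=False, method="approx"
        ).pvalue
        assert p == pytest.approx(ref, rel=1e-10)


class TestVoxelwiseWilcoxon:
    def test_scores_at_reference_value_give_p_one(self):
        masks = [block_mask((3, 3, 3), np.s_[0:2], score=2) for _ in range(5)]
        p, diag = voxelwise_wilcoxon(masks, mu0=2.0)
        tested = np.isfinite(p.data)
        assert np.all(p.data[tested] == 1.0)
        assert diag["degenerate_voxels"] == tested.sum()

    def test_extreme_voxel_matches_enumeration(self):
        # 5 overlapping subjects all with score 0 against mu0=2.5
        masks = [block_mask((3, 3, 3), np.s_[0:1], score=0) for _ in range(5)]
        p, _ = voxelwise_wilcoxon(masks, mu0=2.5)
        expected = signed_rank_p_bruteforce(np.array([-2.5] * 5))
        assert p.data[0, 0, 0] == pytest.approx(expected)

    def test_untested_voxels_are_nan(self, default_cohort):
        masks = default_cohort.masks
        freq = build_frequency_map(masks)
        fm = frequency_mask(freq, len(masks))
        p, _ = voxelwise_wilcoxon(masks, freq_mask=fm)
        assert np.isnan(p.data[np.asarray(fm.data) == 0]).all()
        tested = np.isfinite(p.data)
        assert (p.data[tested] > 0).all() and (p.data[tested] <= 1).all()


class TestSeverityMapSet:
    def test_no_masking_returns_average_map(self, default_cohort):
        ms = build_severity_mapset(default_cohort.masks, alpha=1.0 + 1e-9, fraction=0.0)
        touched = np.asarray(ms.frequency_map.data) > 0
        np.testing.assert_allclose(
            ms.final_map.data[touched], np.nan_to_num(ms.average_map.data)[touched]
        )

    def test_final_map_support_shrinks_with_alpha(self, default_cohort):
        sizes = []
        for alpha in (0.2, 0.05, 0.01):
            ms = build_severity_mapset(default_cohort.masks, alpha=alpha)
            sizes.append(int((ms.final_map.data != 0).sum()))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_final_map_only_where_frequency_and_significance(self, default_cohort):
        ms = build_severity_mapset(default_cohort.masks)
        nonzero = ms.final_map.data != 0
        retained = np.asarray(ms.frequency_map.data) >= ms.threshold_count
        with np.errstate(invalid="ignore"):
            sig = retained & (np.nan_to_num(ms.p_map.data, nan=1.0) < ms.alpha)
        assert np.all(sig[nonzero])

    def test_planted_gradient_yields_posterior_significance(self, default_cohort):
        ms = build_severity_mapset(default_cohort.masks)
        retained = np.asarray(ms.frequency_map.data) >= ms.threshold_count
        sig = ms.final_map.data != 0
        axis = default_cohort.landmarks.axis
        assert sig.sum() > 0
        assert map_centroid(sig.astype(float), axis) > map_centroid(
            retained.astype(float), axis
        )

    def test_shuffled_scores_rarely_significant(self, default_cohort):
        rng = np.random.default_rng(42)
        scores = rng.permutation([m.score for m in default_cohort.masks])
        ms = build_severity_mapset(default_cohort.masks, scores=scores)
        assert significant_fraction(ms) <= 0.07


class TestEngelAssociation:
    def _rec(self, i, score, engel):
        return SubjectRecord(f"s{i}", "left", score, 5.0, 20.0, 2.8, engel_class=engel)

    def test_constant_engel_flagged_degenerate(self):
        recs = [self._rec(i, s, "1") for i, s in enumerate([0, 1, 2, 3, 4, 2])]
        res = engel_ccsfs_association(recs)
        assert res.degenerate and np.isnan(res.rho)

    def test_perfect_antiranking(self):
        # Engel-1 exactly for the low scores -> negative rank association
        recs = [self._rec(i, s, "1" if s <= 1 else "2")
                for i, s in enumerate([0, 0, 1, 3, 4, 4])]
        res = engel_ccsfs_association(recs)
        assert res.rho == pytest.approx(-0.904534, abs=1e-5)

    def test_matches_scipy_on_known_table(self):
        scores = [0, 1, 2, 3, 4, 2, 1, 3]
        engel = ["1", "2", "1", "4", "2", "1", "unknown", "1"]
        recs = [self._rec(i, s, e) for i, (s, e) in enumerate(zip(scores, engel))]
        res = engel_ccsfs_association(recs)
        keep = [i for i, e in enumerate(engel) if e != "unknown"]
        ref = stats.spearmanr(
            [1.0 if engel[i] == "1" else 0.0 for i in keep], [scores[i] for i in keep]
        )
        assert res.rho == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.n == len(keep)
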