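"""Probabilistic voxel-wise mapping of seizure severity from lesion overlap.

The map construction follows four stages:

1. a frequency map counting, at each voxel, how many subjects' lesion masks
   touch it;
2. a frequency mask retaining voxels touched by at least ``ceil(fraction*N)``
   subjects (default 10% of the cohort), which excludes outlier voxels;
3. an average map: at each voxel the severity scores of the overlapping
   subjects are combined by a weighted mean with weights ``1/|lesion|``, so
   larger and less focal lesions are penalized while the map stays on the
   0-4 score scale;
4. a statistical map of two-sided one-sample Wilcoxon signed-rank p-values
   testing, at each voxel, whether the overlapping subjects' scores deviate
   from a reference value (by default the cohort mean score), i.e. whether
   lesion presence at the voxel carries information about severity.

The final map is the average map masked to voxels that survive both the
frequency mask and the p < alpha threshold.

The signed-rank test is computed exactly (full enumeration of the sign-flip
null, via a tied-group convolution that equals the 2^n enumeration) for
samples up to ``exact_max_n`` nonzero differences, and by the normal
approximation with Pratt handling of zero differences above that.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core_volumes import LesionMask, SubjectRecord, VolumeGrid
from .errors import AlignmentError, DataError, ValidationError

P_UNTESTED = np.nan  # sentinel for voxels outside the frequency mask


# ---------------------------------------------------------------------------
# one-sample Wilcoxon signed-rank p-values
# ---------------------------------------------------------------------------

def signed_rank_p(diffs: Sequence[float], exact_max_n: int = 25) -> tuple[float, bool]:
    """Two-sided one-sample signed-rank p-value for a vector of differences.

    Returns ``(p, degenerate)`` where ``degenerate`` is True when fewer than
    two nonzero differences remain (the test is then uninformative and p=1).

    Exact branch (n <= exact_max_n): zero differences are dropped, |d| are
    midranked, and the full distribution of the positive-rank sum under
    independent sign flips is enumerated; the p-value is the probability of
    a statistic at least as far from its null mean as observed.

    Approximate branch: Pratt handling (zeros are ranked together with the
    rest and then dropped from the statistic) with a normal reference whose
    mean and variance are the exact moments of the midrank statistic, which
    incorporates the tie correction automatically. No continuity correction.
    """
    d = np.asarray(diffs, dtype=float)
    values, counts = np.unique(d, return_counts=True)
    return _signed_rank_p_grouped(values, counts, exact_max_n)


def _signed_rank_p_grouped(
    values: np.ndarray, counts: np.ndarray, exact_max_n: int
) -> tuple[float, bool]:
    """Signed-rank p from tied groups of differences (value, multiplicity)."""
    values = np.asarray(values, dtype=float)
    counts = np.asarray(counts, dtype=int)
    nz = np.abs(values) > 1e-12
    n_zero = int(counts[~nz].sum())
    values, counts = values[nz], counts[nz]
    n = int(counts.sum())
    if n < 2:
        return 1.0, True

    order = np.argsort(np.abs(values), kind="stable")
    values, counts = values[order], counts[order]
    # merge groups with equal |d| but opposite sign: same rank, different sign
    absd = np.abs(values)
    # midranks: group g spanning counts, optionally offset by the zeros (Pratt)
    if n <= exact_max_n:
        # exact: zeros dropped before ranking
        ranks = _group_midranks(absd, counts, offset=0)
        w_obs = float(np.sum(counts[values > 0] * ranks[values > 0]))
        return _exact_two_sided_p(ranks, counts, w_obs), False
    # approximate: Pratt, zeros occupy the lowest ranks then are dropped
    ranks = _group_midranks(absd, counts, offset=n_zero)
    w_obs = float(np.sum(counts[values > 0] * ranks[values > 0]))
    mean = float(np.sum(counts * ranks)) / 2.0
    var = float(np.sum(counts * ranks**2)) / 4.0
    if var <= 0:
        return 1.0, True
    z = (w_obs - mean) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z)))), False


def _group_midranks(absd: np.ndarray, counts: np.ndarray, offset: int) -> np.ndarray:
    """Midranks of tied groups sorted by |d|, with ``offset`` lower ranks taken."""
    # groups with identical |d| share a midrank even if signs differ
    ranks = np.empty(len(absd), dtype=float)
    start = offset
    i = 0
    while i < len(absd):
        j = i
        total = 0
        while j < len(absd) and abs(absd[j] - absd[i]) <= 1e-12:
            total += counts[j]
            j += 1
        mid = start + (total + 1) / 2.0
        ranks[i:j] = mid
        start += total
        i = j
    return ranks


def _exact_two_sided_p(ranks: np.ndarray, counts: np.ndarray, w_obs: float) -> float:
    """Exact sign-flip distribution of the positive midrank sum.

    Each of the n nonzero differences flips sign independently with
    probability 1/2 under the null; a tied group of k elements with common
    midrank r therefore contributes ``Binomial(k, 1/2) * 2r`` to the doubled
    statistic. Convolving the per-group distributions gives the exact pmf of
    the 2^n enumeration without enumerating it.
    """
    ranks2 = np.rint(2 * ranks).astype(int)  # doubled midranks are integers
    dist = np.array([1.0])
    for r2, k in zip(ranks2, counts):
        block = np.zeros(k * r2 + 1)
        for j in range(k + 1):
            block[j * r2] += math.comb(k, j) * 0.5**k
        dist = np.convolve(dist, block)
    support = np.arange(dist.size)
    mean2 = float(np.sum(counts * ranks2)) / 2.0
    dev = abs(2.0 * w_obs - mean2)
    return float(dist[np.abs(support - mean2) >= dev - 1e-9].sum())


def signed_rank_p_bruteforce(diffs: Sequence[float]) -> float:
    """Independent oracle: explicit 2^n enumeration of sign assignments.

    Only feasible for small n; used to validate :func:`signed_rank_p`.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.abs(d) > 1e-12]
    n = len(d)
    if n < 2:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean = ranks.sum() / 2.0
    dev = abs(w_obs - mean)
    count = 0
    for signs in range(2**n):
        w = sum(ranks[i] for i in range(n) if (signs >> i) & 1)
        if abs(w - mean) >= dev - 1e-9:
            count += 1
    return count / 2**n


# ---------------------------------------------------------------------------
# map construction
# ---------------------------------------------------------------------------

def _stack_masks(masks: Sequence[LesionMask]) -> tuple[np.ndarray, VolumeGrid]:
    if len(masks) == 0:
        raise DataError("at least one lesion mask is required")
    ref = masks[0].grid
    for m in masks[1:]:
        ref.check_aligned(m.grid)
    stack = np.stack([m.indicator for m in masks])
    return stack, ref


def build_frequency_map(masks: Sequence[LesionMask]) -> VolumeGrid:
    """Per-voxel count of lesion masks in contact with the voxel."""
    stack, ref = _stack_masks(masks)
    return ref.like(stack.sum(axis=0).astype(np.int32))


def frequency_threshold(n_subjects: int, fraction: float = 0.10) -> int:
    """Minimum overlap count for retention: ceil(fraction * N), at least 1."""
    return max(1, math.ceil(fraction * n_subjects))


def frequency_mask(
    freq: VolumeGrid, n_subjects: int, fraction: float = 0.10
) -> VolumeGrid:
    """Binary mask of voxels touched by at least ``ceil(fraction*N)`` subjects."""
    thr = frequency_threshold(n_subjects, fraction)
    return freq.like((np.asarray(freq.data) >= thr).astype(np.uint8))


def build_average_map(
    masks: Sequence[LesionMask],
    scores: Sequence[int] | None = None,
    size_normalize: bool = True,
    normalization: str = "weighted_mean",
) -> VolumeGrid:
    """Score-weighted average map; NaN where no mask overlaps.

    ``normalization='weighted_mean'`` (default) computes, at voxel v,
    ``sum_i w_i s_i / sum_i w_i`` over the subjects i whose mask covers v,
    with ``w_i = 1/|X_i|`` when ``size_normalize`` (else 1). The alternative
    ``'mean_of_scaled'`` divides each score by the lesion size before a plain
    mean, leaving the map on an arbitrary scale.
    """
    stack, ref = _stack_masks(masks)
    s = np.asarray([m.score for m in masks] if scores is None else list(scores), dtype=float)
    if len(s) != len(masks):
        raise ValidationError("one score per mask is required")
    if np.any((s < 0) | (s > 4)):
        raise ValidationError("scores must lie in 0..4")
    sizes = stack.reshape(len(masks), -1).sum(axis=1).astype(float)
    w = 1.0 / sizes if size_normalize else np.ones_like(sizes)
    flat = stack.reshape(len(masks), -1).astype(float)
    if normalization == "weighted_mean":
        num = (w * s) @ flat
        den = w @ flat
    elif normalization == "mean_of_scaled":
        num = (w * s) @ flat
        den = flat.sum(axis=0)
    else:
        raise ValidationError(f"unknown normalization {normalization!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return ref.like(avg.reshape(ref.shape))


def voxelwise_wilcoxon(
    masks: Sequence[LesionMask],
    scores: Sequence[int] | None = None,
    freq_mask: VolumeGrid | None = None,
    mu0: float | None = None,
    exact_max_n: int = 25,
) -> tuple[VolumeGrid, dict]:
    """Per-voxel signed-rank p-values of overlapping scores against ``mu0``.

    At each retained voxel the sample is the set of scores of the subjects
    whose lesion covers the voxel, tested two-sided against the reference
    value ``mu0`` (cohort mean score by default). Voxels outside the
    frequency mask carry NaN ("untested", distinct from "tested, null").
    Retained voxels with fewer than two nonzero differences get p = 1 and
    are counted in the diagnostics.

    Because scores take only five values, a voxel's p depends only on the
    per-value counts of its sample; voxels are grouped by that count vector
    so each distinct configuration is evaluated once.
    """
    stack, ref = _stack_masks(masks)
    s = np.asarray([m.score for m in masks] if scores is None else list(scores), dtype=float)
    if mu0 is None:
        mu0 = float(np.mean(s))
    if freq_mask is None:
        retain = stack.any(axis=0)
    else:
        ref.check_aligned(freq_mask)
        retain = np.asarray(freq_mask.data) > 0
    flat = stack.reshape(len(masks), -1)
    retain_flat = retain.reshape(-1)
    idx = np.flatnonzero(retain_flat)

    score_values = np.unique(s)
    onehot = (s[:, None] == score_values[None, :]).astype(np.int64)  # (N, K)
    counts = flat[:, idx].T.astype(np.int64) @ onehot  # (V_retained, K)

    uniq, inverse = np.unique(counts, axis=0, return_inverse=True)
    diffs_values = score_values - mu0
    p_uniq = np.empty(len(uniq))
    degen_uniq = np.empty(len(uniq), dtype=bool)
    for k, row in enumerate(uniq):
        p_uniq[k], degen_uniq[k] = _signed_rank_p_grouped(diffs_values, row, exact_max_n)
    p_flat = np.full(flat.shape[1], P_UNTESTED)
    p_flat[idx] = p_uniq[inverse]
    diagnostics = {
        "tested_voxels": int(len(idx)),
        "degenerate_voxels": int(degen_uniq[inverse].sum()),
        "mu0": float(mu0),
        "unique_samples": int(len(uniq)),
    }
    return ref.like(p_flat.reshape(ref.shape)), diagnostics


@dataclasses.dataclass
class SeverityMapSet:
    """The four maps of the probabilistic severity analysis plus parameters."""

    average_map: VolumeGrid
    frequency_map: VolumeGrid
    p_map: VolumeGrid
    final_map: VolumeGrid
    alpha: float
    fraction: float
    mu0: float
    n_subjects: int
    threshold_count: int
    diagnostics: dict


def build_severity_mapset(
    masks: Sequence[LesionMask],
    scores: Sequence[int] | None = None,
    alpha: float = 0.05,
    fraction: float = 0.10,
    mu0: float | None = None,
    size_normalize: bool = True,
    exact_max_n: int = 25,
) -> SeverityMapSet:
    """Compose frequency, average, and statistical maps into the final map.

    The final map equals the average map on voxels passing both the
    frequency mask and p < alpha, and 0 elsewhere.
    """
    freq = build_frequency_map(masks)
    n = len(masks)
    fmask = frequency_mask(freq, n, fraction)
    avg = build_average_map(masks, scores, size_normalize=size_normalize)
    p_map, diagnostics = voxelwise_wilcoxon(
        masks, scores, freq_mask=fmask, mu0=mu0, exact_max_n=exact_max_n
    )
    with np.errstate(invalid="ignore"):
        sig = (np.asarray(fmask.data) > 0) & (np.asarray(p_map.data) < alpha)
    final = np.where(sig, np.nan_to_num(avg.data), 0.0)
    return SeverityMapSet(
        average_map=avg,
        frequency_map=freq,
        p_map=p_map,
        final_map=freq.like(final),
        alpha=alpha,
        fraction=fraction,
        mu0=diagnostics["mu0"],
        n_subjects=n,
        threshold_count=frequency_threshold(n, fraction),
        diagnostics=diagnostics,
    )


def significant_fraction(mapset: SeverityMapSet) -> float:
    """Fraction of frequency-retained voxels with p < alpha."""
    retained = np.asarray(mapset.frequency_map.data) >= mapset.threshold_count
    if retained.sum() == 0:
        return 0.0
    with np.errstate(invalid="ignore"):
        sig = retained & (np.asarray(mapset.p_map.data) < mapset.alpha)
    return float(sig.sum() / retained.sum())


def map_centroid(data: np.ndarray, axis: int, weights: np.ndarray | None = None) -> float:
    """Intensity-weighted centroid slice index of a nonnegative map along ``axis``."""
    w = np.asarray(data, dtype=float) if weights is None else np.asarray(weights, dtype=float)
    w = np.nan_to_num(w)
    if w.sum() <= 0:
        return float("nan")
    other = tuple(a for a in range(w.ndim) if a != axis)
    profile = w.sum(axis=other)
    return float(np.average(np.arange(len(profile)), weights=profile))


# ---------------------------------------------------------------------------
# Engel outcome vs severity score
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AssociationResult:
    rho: float
    p_value: float
    n: int
    degenerate: bool


def engel_ccsfs_association(records: Iterable[SubjectRecord]) -> AssociationResult:
    """Rank correlation between the Engel-1 (seizure-free) indicator and score.

    Subjects with unknown Engel class are excluded. A constant column on
    either side makes the correlation undefined; the result is flagged
    rather than raising, since this is a reported (not thresholded) check.
    """
    pairs = [
        (1.0 if r.engel_class == "1" else 0.0, float(r.score))
        for r in records
        if r.engel_class != "unknown"
    ]
    if len(pairs) < 2:
        return AssociationResult(float("nan"), float("nan"), len(pairs), True)
    engel, score = map(np.asarray, zip(*pairs))
    if np.all(engel == engel[0]) or np.all(score == score[0]):
        return AssociationResult(float("nan"), float("nan"), len(pairs), True)
    rho, p = stats.spearmanr(engel, score)
    return AssociationResult(float(rho), float(p), len(pairs), False)
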