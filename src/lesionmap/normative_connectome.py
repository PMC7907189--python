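"""Seed-based normative connectivity maps and the left/right laterality contrast.

Each patient's lesion mask serves as a seed into a normative resting-state
BOLD dataset: per normative subject, the seed's mean time series is
correlated with every voxel's series; the per-voxel Pearson correlations are
pooled across normative subjects by Fisher-z averaging and transformed back
to r. The group question — do right-sided seizure foci show greater
brain-wide connectivity than left-sided ones? — is answered voxel-wise by a
logistic regression of seed laterality on the (Fisher-z) connectivity
values, with Benjamini-Hochberg FDR control over voxels.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_volumes import LesionMask, VolumeGrid
from .errors import CoverageError, DataError, DesignError, ValidationError

R_CLIP = 1.0 - 1e-7  # keeps arctanh finite on numerically perfect correlations


@dataclasses.dataclass
class ConnectivityMap:
    """Whole-brain correlation map for one patient seed.

    ``grid`` holds Pearson r in [-1, 1]; voxels inside the seed itself, and
    voxels with zero variance in every normative subject, are NaN.
    """

    grid: VolumeGrid
    seed_subject_id: str
    laterality: str

    def fisher_z(self) -> np.ndarray:
        r = np.clip(np.asarray(self.grid.data, dtype=float), -R_CLIP, R_CLIP)
        return np.arctanh(r)


@dataclasses.dataclass
class LateralityContrast:
    """Voxel-wise laterality contrast: Wald statistics, p-values, FDR mask.

    Sign convention: positive statistic = greater connectivity for
    right-sided seeds.
    """

    stat_map: VolumeGrid
    p_map: VolumeGrid
    fdr_mask: VolumeGrid
    q: float
    diagnostics: dict


def _as_4d(bold) -> np.ndarray:
    if isinstance(bold, (str, Path)):
        bold = np.asanyarray(nib.load(str(bold)).dataobj)
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 4:
        raise ValidationError(f"expected a 4D BOLD volume, got shape {bold.shape}")
    return bold


def seed_timeseries(seed: LesionMask | np.ndarray, bold) -> np.ndarray:
    """Unweighted mean BOLD series over the seed voxels."""
    bold = _as_4d(bold)
    ind = seed.indicator if isinstance(seed, LesionMask) else np.asarray(seed, dtype=bool)
    if ind.shape != bold.shape[:3]:
        raise CoverageError(
            f"seed shape {ind.shape} does not match BOLD field of view {bold.shape[:3]}"
        )
    if not ind.any():
        raise CoverageError("seed has no voxels inside the BOLD field of view")
    return bold[ind].mean(axis=0)


def _iter_normative(normative) -> Iterable[np.ndarray]:
    if isinstance(normative, (str, Path)):
        paths = sorted(Path(normative).glob("*.nii*"))
        if not paths:
            raise DataError(f"normative directory {normative} contains no NIfTI volumes")
        for p in paths:
            yield _as_4d(p)
    else:
        items = list(normative)
        if not items:
            raise DataError("normative dataset is empty")
        for item in items:
            yield _as_4d(item)


def pearson_map(seed_series: np.ndarray, bold: np.ndarray) -> np.ndarray:
    """Pearson r between one series and every voxel series; NaN at zero variance."""
    t = len(seed_series)
    s = seed_series - seed_series.mean()
    s_sd = s.std()
    x = bold - bold.mean(axis=-1, keepdims=True)
    x_sd = x.std(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ s) / (t * x_sd * s_sd)
    if s_sd == 0:
        r[:] = np.nan
    r[x_sd == 0] = np.nan
    return r


def rmap(
    seed: LesionMask,
    normative,
    grid: VolumeGrid | None = None,
    mask_seed_voxels: bool = True,
) -> ConnectivityMap:
    """Seed r-map pooled over the normative dataset.

    Per normative subject, Pearson r of the seed's mean series against every
    voxel; voxels with zero variance in a subject are excluded from that
    subject's contribution. Pooling is the mean of Fisher z across subjects,
    transformed back to r (variance-stabilized averaging). ``normative`` may
    be a directory of 4D NIfTI files or an iterable of 4D arrays/paths.
    """
    z_sum = None
    z_count = None
    for bold in _iter_normative(normative):
        series = seed_timeseries(seed, bold)
        r = pearson_map(series, bold)
        z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
        finite = np.isfinite(z)
        if z_sum is None:
            z_sum = np.zeros(z.shape)
            z_count = np.zeros(z.shape, dtype=int)
        z_sum[finite] += z[finite]
        z_count[finite] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        r_agg = np.tanh(np.where(z_count > 0, z_sum / np.maximum(z_count, 1), np.nan))
    if mask_seed_voxels:
        r_agg[seed.indicator] = np.nan
    base = seed.grid if grid is None else grid
    return ConnectivityMap(
        grid=base.like(r_agg),
        seed_subject_id=seed.subject_id,
        laterality=seed.laterality,
    )


# ---------------------------------------------------------------------------
# voxel-wise logistic regression of laterality on connectivity
# ---------------------------------------------------------------------------

def _logistic_wald(
    y: np.ndarray,
    x: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    diverge_norm: float = 50.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-column logistic fit logit P(y=1) = b0 + b1 * x[:, v].

    The covariate is standardized per column before fitting (the Wald
    statistic is invariant to this), so the coefficient-norm divergence
    check operates on a common scale. Newton/IRLS with closed-form 2x2
    solves; returns (wald_z, lr_pvalue, b1, converged, separated) per
    column. Inference uses the likelihood-ratio p-value: at n of a few
    dozen the Wald p-value is non-monotone in the effect size (the
    Hauck-Donner phenomenon caps |z| near 3), whereas the LR statistic
    remains monotone; the Wald z is still reported as the signed
    effect-size map.
    """
    n, v = x.shape
    mu_x = x.mean(axis=0)
    sd_x = x.std(axis=0)
    ok = sd_x > 0
    xs = np.where(ok, (x - mu_x) / np.where(ok, sd_x, 1.0), 0.0)
    b0 = np.zeros(v)
    b1 = np.zeros(v)
    yv = y[:, None].astype(float)
    converged = np.zeros(v, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(b0[None, :] + b1[None, :] * xs, -35.0, 35.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        s0 = w.sum(axis=0)
        s1 = (w * xs).sum(axis=0)
        s2 = (w * xs * xs).sum(axis=0)
        resid = yv - mu
        g0 = resid.sum(axis=0)
        g1 = (resid * xs).sum(axis=0)
        det = s0 * s2 - s1 * s1
        bad = det <= 1e-12
        det_safe = np.where(bad, 1.0, det)
        d0 = (s2 * g0 - s1 * g1) / det_safe
        d1 = (s0 * g1 - s1 * g0) / det_safe
        d0[bad] = 0.0
        d1[bad] = 0.0
        step = ~converged
        b0 = b0 + d0 * step
        b1 = b1 + d1 * step
        converged = converged | (np.maximum(np.abs(d0), np.abs(d1)) < tol)
        if converged.all():
            break
    separated = (np.abs(b1) > diverge_norm) | ~converged | ~ok
    # final information matrix for standard errors, and log-likelihoods
    eta = np.clip(b0[None, :] + b1[None, :] * xs, -35.0, 35.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    s0 = w.sum(axis=0)
    s1 = (w * xs).sum(axis=0)
    s2 = (w * xs * xs).sum(axis=0)
    det = s0 * s2 - s1 * s1
    with np.errstate(invalid="ignore", divide="ignore"):
        se1 = np.sqrt(np.where(det > 0, s0 / np.where(det > 0, det, 1.0), np.nan))
        wald = b1 / se1
    separated |= ~np.isfinite(wald)
    ll1 = (yv * eta - np.log1p(np.exp(eta))).sum(axis=0)
    p_hat = y.mean()
    ll0 = n * (p_hat * np.log(p_hat) + (1.0 - p_hat) * np.log(1.0 - p_hat))
    lr = np.maximum(2.0 * (ll1 - ll0), 0.0)
    lr_p = stats.chi2.sf(lr, df=1)
    return wald, lr_p, b1, converged, separated


def fdr_correct(p_values, q: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level ``q`` (boolean array)."""
    p = np.asarray(list(p_values) if not isinstance(p_values, np.ndarray) else p_values,
                   dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def laterality_contrast(
    rmaps: Sequence[ConnectivityMap],
    labels: Sequence[str] | None = None,
    q: float = 0.01,
    method: str = "logistic",
) -> LateralityContrast:
    """Voxel-wise contrast of right- vs left-seeded connectivity maps.

    ``method='logistic'`` regresses the laterality indicator (right = 1) on
    the Fisher-z connectivity values at each voxel and reports the slope's
    Wald z statistic with a two-sided p-value. Voxels with complete
    separation or non-convergence are flagged and excluded from the FDR
    step (counted in the diagnostics). ``method='ranksum'`` is a two-sample
    Mann-Whitney alternative for comparison.
    """
    if len(rmaps) < 4:
        raise DataError("need at least two maps per laterality class")
    labs = [m.laterality for m in rmaps] if labels is None else list(labels)
    y = np.asarray([1.0 if l == "right" else 0.0 for l in labs])
    if len(set(labs)) < 2:
        raise DesignError("laterality labels contain a single class")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise DesignError("need at least two maps per laterality class")
    ref = rmaps[0].grid
    for m in rmaps[1:]:
        ref.check_aligned(m.grid)
    z = np.stack([m.fisher_z().reshape(-1) for m in rmaps])  # (N, V)
    defined = np.isfinite(z).all(axis=0)
    varying = defined & (z.std(axis=0) > 1e-12)  # tolerance absorbs arctanh round-off
    idx = np.flatnonzero(varying)

    stat = np.full(z.shape[1], np.nan)
    p = np.full(z.shape[1], np.nan)
    n_flagged = 0
    if method == "logistic":
        wald, lr_p, _, _, separated = _logistic_wald(y, z[:, idx])
        usable = ~separated
        stat[idx] = np.where(usable, wald, np.nan)
        p[idx[usable]] = lr_p[usable]
        n_flagged = int(separated.sum())
    elif method == "ranksum":
        right = z[y == 1][:, idx]
        left = z[y == 0][:, idx]
        res = stats.mannwhitneyu(right, left, axis=0, alternative="two-sided")
        u1 = res.statistic
        mu_u = right.shape[0] * left.shape[0] / 2.0
        stat[idx] = np.sign(u1 - mu_u) * stats.norm.isf(np.minimum(res.pvalue, 1.0) / 2.0)
        p[idx] = res.pvalue
    else:
        raise ValidationError(f"unknown method {method!r}")

    tested = np.isfinite(p)
    fdr = np.zeros(z.shape[1], dtype=bool)
    if tested.any():
        fdr[tested] = fdr_correct(p[tested], q=q)
    shape = ref.shape
    return LateralityContrast(
        stat_map=ref.like(stat.reshape(shape)),
        p_map=ref.like(p.reshape(shape)),
        fdr_mask=ref.like(fdr.reshape(shape).astype(np.uint8)),
        q=q,
        diagnostics={
            "n_maps": len(rmaps),
            "n_right": int((y == 1).sum()),
            "n_left": int((y == 0).sum()),
            "tested_voxels": int(tested.sum()),
            "flagged_voxels": n_flagged,
            "undefined_voxels": int((~varying).sum()),
            "method": method,
        },
    )
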