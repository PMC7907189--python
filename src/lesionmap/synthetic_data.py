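"""Synthetic cohorts with planted effects for every pipeline stage.

The generator emulates the study conditions end to end so that each
analysis stage can be exercised and validated offline:

* binary hippocampal lesion masks on a common 1 mm grid, one contiguous
  run of coronal slices per subject anchored at the anterior end of a
  hemisphere-specific hippocampal footprint, with a variable posterior
  extent fraction ``f`` (sclerosis always involves the head and extends a
  variable distance toward the tail);
* a 0-4 severity score generated from a latent ``intercept - beta * f``
  plus Gaussian noise, rounded and clipped, so greater posterior extent
  plants a lower score;
* per-subject mean cortical thickness declining linearly with disease
  duration, with an additional (steeper) decline for right-sided foci;
* a normative resting-state surrogate: per normative subject, white noise
  plus shared latent time series injected into seed footprints and into
  target regions, with the right-seeded network broadcast to a strictly
  larger target set than the left-seeded one.

The BOLD surrogate lives on its own coarser grid (3 mm, matching typical
EPI resolution) and patient seeds for the connectome analysis are drawn
directly on that grid; spatial normalization between native and BOLD
space is out of scope throughout the package.

All generators are deterministic: identical config + seed give identical
outputs. Per-stage substreams are derived from the master seed, so e.g.
the lesion geometry does not change when only the BOLD model is altered.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_volumes import (
    LesionMask,
    SubfieldLandmarks,
    SubjectRecord,
    VolumeGrid,
    write_mask,
    write_table,
)
from .errors import ConfigError

# Engel class frequencies of the emulated cohort: mostly seizure-free at
# one year, a few class 2/4, a few unknown.
ENGEL_PROBS = {"1": 29 / 35, "2": 2 / 35, "3": 0.0, "4": 2 / 35, "unknown": 2 / 35}


@dataclasses.dataclass(frozen=True)
class Footprint:
    """An axis-aligned box of voxels hosting one hemisphere's hippocampus."""

    x: tuple[int, int]  # inclusive bounds
    y: tuple[int, int]  # anterior .. posterior slice span (AP axis)
    z: tuple[int, int]

    def check(self, shape: tuple[int, int, int]) -> None:
        for (lo, hi), n in zip((self.x, self.y, self.z), shape):
            if not (0 <= lo <= hi < n):
                raise ConfigError(f"footprint {self} empty or outside grid {shape}")


@dataclasses.dataclass(frozen=True)
class SeverityModel:
    """Latent severity: ``intercept - beta_posterior * f + Normal(0, noise_sd)``."""

    intercept: float = 3.5
    beta_posterior: float = 3.0
    noise_sd: float = 0.7


@dataclasses.dataclass(frozen=True)
class ThicknessModel:
    """Mean thickness (mm) linear in duration with a right-laterality interaction."""

    base_mm: float = 3.0
    slope_per_year: float = -0.008
    extra_right_slope: float = -0.006
    residual_sd: float = 0.08


@dataclasses.dataclass(frozen=True)
class BoldModel:
    """Normative BOLD surrogate parameters (3 mm grid, 124 time points)."""

    n_subjects: int = 20
    n_timepoints: int = 124
    shape: tuple[int, int, int] = (12, 15, 12)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    noise_sd: float = 1.0
    #: amplitude of the per-slice hippocampal network latents in seed voxels;
    #: each footprint slice carries its own latent, so two patients share
    #: network signal only through overlapping seed slices
    seed_amplitude: float = 1.0
    #: amplitude of the global (hemisphere-shared) latent in seed voxels; it
    #: cancels in the left/right contrast but gives both classes a nonzero
    #: baseline correlation with every target, so class distributions overlap
    global_seed_coupling: float = 0.3
    global_target_coupling: float = 0.35
    #: target loadings on the posterior-weighted sum of the same side's slice
    #: latents; the right-sided network is both stronger and broadcast to a
    #: strictly larger target set
    left_target_amplitude: float = 0.28
    right_target_amplitude: float = 0.35
    #: per-voxel idiosyncratic signal inside seed footprints; sized so the
    #: network latents carry only ~10% of a seed's variance, which keeps
    #: patient r-maps heterogeneous within a laterality class (a class-common
    #: normative-sampling fingerprint would otherwise dominate the voxel-wise
    #: contrast at unconnected voxels)
    local_amplitude: float = 6.7
    seed_window_slices: int = 3  # slice depth of each patient's BOLD-grid seed
    #: posterior ramp of the target loadings across footprint slices: the
    #: posterior (tail) end of the hippocampus drives the target networks
    #: hardest, so posterior seeds are the best connected
    posterior_ramp: tuple[float, float] = (0.25, 1.0)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the analyzed cohort: 35 subjects, 15 of them with a
    right-sided focus, disease duration spanning 2-46 years, and a 20
    subject normative BOLD sample.
    """

    seed: int = 0
    n_subjects: int = 35
    p_right: float = 15 / 35
    grid_shape: tuple[int, int, int] = (48, 56, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ap_axis: int = 1
    anterior_direction: str = "decreasing"  # anterior = low slice index
    left_footprint: Footprint = Footprint(x=(7, 15), y=(14, 41), z=(18, 26))
    right_footprint: Footprint = Footprint(x=(32, 40), y=(14, 41), z=(18, 26))
    head_body_boundary: int = 23
    body_tail_boundary: int = 33
    min_posterior_fraction: float = 0.05
    inplane_radius_range: tuple[float, float] = (2.3, 4.3)
    severity: SeverityModel = SeverityModel()
    thickness: ThicknessModel = ThicknessModel()
    duration_range: tuple[float, float] = (2.0, 46.0)
    onset_range: tuple[float, float] = (1.0, 30.0)
    duration_right_shift: float = 0.0  # optional laterality-duration coupling, years
    p_female: float = 16 / 35
    bold: BoldModel = BoldModel()

    def __post_init__(self):
        if not 0.0 <= self.p_right <= 1.0:
            raise ConfigError("p_right must be a probability")
        if not 0.0 <= self.p_female <= 1.0:
            raise ConfigError("p_female must be a probability")
        if self.severity.noise_sd < 0 or self.thickness.residual_sd < 0:
            raise ConfigError("noise scales must be >= 0")
        self.left_footprint.check(self.grid_shape)
        self.right_footprint.check(self.grid_shape)

    def reference_grid(self) -> VolumeGrid:
        return VolumeGrid(np.zeros(self.grid_shape, dtype=np.uint8), spacing=self.spacing)

    def landmarks(self) -> SubfieldLandmarks:
        return SubfieldLandmarks(
            axis=self.ap_axis,
            head_body_boundary=self.head_body_boundary,
            body_tail_boundary=self.body_tail_boundary,
            anterior_direction=self.anterior_direction,
        )


def _rng(seed: int, stage: int) -> np.random.Generator:
    """Independent per-stage substream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))


# ---------------------------------------------------------------------------
# lesion masks
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LesionSimulation:
    masks: list[LesionMask]
    landmarks: SubfieldLandmarks
    posterior_extent: np.ndarray  # planted f per subject, in [0, 1]
    lateralities: list[str]


def simulate_lesions(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> LesionSimulation:
    """Simulate one contiguous-slice-run lesion mask per subject.

    Each mask occupies slices from the anterior end of its hemisphere's
    footprint to a posterior extent ``f`` drawn uniformly, with an
    elliptical in-plane cross-section of jittered center and radii.
    """
    rng = _rng(cfg.seed, 0) if rng is None else rng
    ref = cfg.reference_grid()
    masks: list[LesionMask] = []
    fs = np.empty(cfg.n_subjects)
    lats: list[str] = []
    y0, y1 = cfg.left_footprint.y
    span = y1 - y0
    for i in range(cfg.n_subjects):
        right = bool(rng.random() < cfg.p_right)
        fp = cfg.right_footprint if right else cfg.left_footprint
        f = float(rng.uniform(cfg.min_posterior_fraction, 1.0))
        b = y0 + int(round(f * span))
        cx = (fp.x[0] + fp.x[1]) / 2.0 + rng.integers(-1, 2)
        cz = (fp.z[0] + fp.z[1]) / 2.0 + rng.integers(-1, 2)
        rx, rz = rng.uniform(*cfg.inplane_radius_range, size=2)
        xs = np.arange(fp.x[0], fp.x[1] + 1)
        zs = np.arange(fp.z[0], fp.z[1] + 1)
        inplane = (
            ((xs[:, None] - cx) / rx) ** 2 + ((zs[None, :] - cz) / rz) ** 2
        ) <= 1.0
        data = np.zeros(cfg.grid_shape, dtype=np.uint8)
        block = data[fp.x[0] : fp.x[1] + 1, :, fp.z[0] : fp.z[1] + 1]
        block[:, y0 : b + 1, :] = inplane[:, None, :]
        fs[i] = (b - y0) / span
        lats.append("right" if right else "left")
        masks.append(
            LesionMask(
                grid=ref.like(data),
                subject_id=f"sub-{i + 1:03d}",
                laterality=lats[-1],
                score=0,
            )
        )
    return LesionSimulation(masks=masks, landmarks=cfg.landmarks(), posterior_extent=fs, lateralities=lats)


def simulate_scores(
    posterior_extent: Sequence[float],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Severity scores 0-4 anticorrelated with posterior lesion extent."""
    rng = _rng(cfg.seed, 1) if rng is None else rng
    f = np.asarray(posterior_extent, dtype=float)
    m = cfg.severity
    latent = m.intercept - m.beta_posterior * f
    if m.noise_sd > 0:
        latent = latent + rng.normal(0.0, m.noise_sd, size=f.shape)
    return np.clip(np.rint(latent), 0, 4).astype(int)


def simulate_thickness(
    durations: Sequence[float],
    lateralities: Sequence[str],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mean cortical thickness (mm), linear in duration, steeper on the right."""
    rng = _rng(cfg.seed, 2) if rng is None else rng
    d = np.asarray(durations, dtype=float)
    right = np.asarray([l == "right" for l in lateralities], dtype=float)
    m = cfg.thickness
    mu = m.base_mm + m.slope_per_year * d + m.extra_right_slope * d * right
    if m.residual_sd > 0:
        mu = mu + rng.normal(0.0, m.residual_sd, size=d.shape)
    return mu


# ---------------------------------------------------------------------------
# full tabular cohort
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimulatedCohort:
    masks: list[LesionMask]
    landmarks: SubfieldLandmarks
    records: list[SubjectRecord]
    truth: dict


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Masks, scores, demographics, and thickness for one synthetic cohort."""
    from .core_volumes import assign_subfields, lesion_volume_cc

    lesions = simulate_lesions(cfg)
    scores = simulate_scores(lesions.posterior_extent, cfg)
    rng_demo = _rng(cfg.seed, 3)
    n = cfg.n_subjects
    onset = rng_demo.uniform(*cfg.onset_range, size=n)
    duration = rng_demo.uniform(*cfg.duration_range, size=n)
    right = np.array([l == "right" for l in lesions.lateralities])
    if cfg.duration_right_shift:
        duration = np.clip(
            duration + cfg.duration_right_shift * right, cfg.duration_range[0], None
        )
    sex = np.where(rng_demo.random(n) < cfg.p_female, "F", "M")
    engel_names = list(ENGEL_PROBS)
    engel = rng_demo.choice(engel_names, size=n, p=list(ENGEL_PROBS.values()))
    thickness = simulate_thickness(duration, lesions.lateralities, cfg)

    masks: list[LesionMask] = []
    records: list[SubjectRecord] = []
    for i, mask in enumerate(lesions.masks):
        mask = dataclasses.replace(mask, score=int(scores[i]))
        masks.append(mask)
        head, body, tail = assign_subfields(mask, lesions.landmarks)
        records.append(
            SubjectRecord(
                subject_id=mask.subject_id,
                laterality=mask.laterality,
                score=int(scores[i]),
                age_at_onset=float(onset[i]),
                age_at_surgery=float(onset[i] + duration[i]),
                mean_thickness=float(thickness[i]),
                engel_class=str(engel[i]),
                sex=str(sex[i]),
                lesion_volume=lesion_volume_cc(mask),
                has_head=head,
                has_body=body,
                has_tail=tail,
            )
        )
    truth = {
        "posterior_extent": lesions.posterior_extent.tolist(),
        "severity": dataclasses.asdict(cfg.severity),
        "thickness": dataclasses.asdict(cfg.thickness),
        "seed": cfg.seed,
    }
    return SimulatedCohort(masks=masks, landmarks=lesions.landmarks, records=records, truth=truth)


# ---------------------------------------------------------------------------
# normative BOLD surrogate
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConnectomeLayout:
    """Seed footprints, target regions, and latent loadings on the BOLD grid.

    The latent basis is one global time series (index 0) followed by one
    latent per footprint slice and side: a patient's seed window picks up
    the latents of the slices it covers, so two same-side patients share
    network signal only where their windows overlap. Target regions load on
    the posterior-weighted sum of their side's slice latents plus the global
    latent.
    """

    grid: VolumeGrid
    left_seed: np.ndarray  # bool footprints
    right_seed: np.ndarray
    left_targets: np.ndarray
    right_targets: np.ndarray
    loadings: np.ndarray  # (nx, ny, nz, n_latents) latent weights

    def __post_init__(self):
        regions = [self.left_seed, self.right_seed, self.left_targets, self.right_targets]
        total = sum(r.astype(int) for r in regions)
        if total.max() > 1:
            raise ConfigError("seed and target regions overlap")

    @property
    def n_latents(self) -> int:
        return self.loadings.shape[-1]


def _box(arr: np.ndarray, x: tuple[int, int], y: tuple[int, int], z: tuple[int, int]) -> None:
    arr[x[0] : x[1] + 1, y[0] : y[1] + 1, z[0] : z[1] + 1] = True


def connectome_layout(cfg: SimulationConfig) -> ConnectomeLayout:
    """Default seed/target geometry on the BOLD grid.

    Left and right hippocampal seed footprints are 5x7x5 voxel boxes; the
    right-seeded network projects to three 4x3x3 target boxes (108 voxels)
    and the left-seeded network to one (36 voxels), planting the greater
    brain-wide connectivity of the right seed.
    """
    b = cfg.bold
    shape = b.shape
    grid = VolumeGrid(np.zeros(shape, dtype=np.uint8), spacing=b.spacing)
    left_seed = np.zeros(shape, dtype=bool)
    right_seed = np.zeros(shape, dtype=bool)
    left_targets = np.zeros(shape, dtype=bool)
    right_targets = np.zeros(shape, dtype=bool)
    # 5x5 in-plane footprints: patient seed windows (2x2 in-plane) then share
    # few voxels, keeping same-side r-maps decorrelated at unconnected voxels
    _box(left_seed, (0, 4), (4, 10), (3, 7))
    _box(right_seed, (7, 11), (4, 10), (3, 7))
    _box(left_targets, (0, 3), (0, 2), (9, 11))
    _box(right_targets, (0, 3), (12, 14), (1, 3))
    _box(right_targets, (8, 11), (0, 2), (9, 11))
    _box(right_targets, (4, 7), (11, 13), (8, 10))

    ys = np.arange(4, 11)  # footprint slices, anterior -> posterior
    n_slices = len(ys)
    # latent 0: global; 1..n: left slice latents; n+1..2n: right slice latents
    loadings = np.zeros((*shape, 1 + 2 * n_slices), dtype=float)
    ramp = np.linspace(*b.posterior_ramp, n_slices)
    ramp_norm = ramp / np.sqrt((ramp**2).sum())
    for side_idx, (seed, targets, target_amp) in enumerate(
        (
            (left_seed, left_targets, b.left_target_amplitude),
            (right_seed, right_targets, b.right_target_amplitude),
        )
    ):
        base = 1 + side_idx * n_slices
        for j, y in enumerate(ys):
            sl = seed[:, y, :]
            loadings[:, y, :, 0][sl] += b.global_seed_coupling
            loadings[:, y, :, base + j][sl] += b.seed_amplitude
            loadings[..., base + j][targets] += target_amp * ramp_norm[j]
        loadings[..., 0][targets] += b.global_target_coupling
    return ConnectomeLayout(
        grid=grid,
        left_seed=left_seed,
        right_seed=right_seed,
        left_targets=left_targets,
        right_targets=right_targets,
        loadings=loadings,
    )


def simulate_normative_bold(
    cfg: SimulationConfig,
    layout: ConnectomeLayout | None = None,
    rng: np.random.Generator | None = None,
    out_dir: str | Path | None = None,
) -> list[np.ndarray]:
    """Generate the normative 4D series (one run per normative subject).

    Each subject's data are white noise plus the latent time series
    injected according to the layout's per-voxel loadings, plus an
    idiosyncratic per-voxel signal inside the seed footprints (so patients
    averaging different voxel subsets get genuinely different seed series).
    When ``out_dir`` is given the volumes are also written as 4D NIfTI
    files.
    """
    layout = connectome_layout(cfg) if layout is None else layout
    rng = _rng(cfg.seed, 4) if rng is None else rng
    b = cfg.bold
    footprint = layout.left_seed | layout.right_seed
    n_fp = int(footprint.sum())
    series: list[np.ndarray] = []
    for s in range(b.n_subjects):
        latents = rng.normal(size=(layout.n_latents, b.n_timepoints))
        data = rng.normal(scale=b.noise_sd, size=(*b.shape, b.n_timepoints)) if b.noise_sd > 0 else np.zeros((*b.shape, b.n_timepoints))
        data += np.tensordot(layout.loadings, latents, axes=(3, 0))
        if b.local_amplitude > 0 and n_fp:
            data[footprint] += b.local_amplitude * rng.normal(size=(n_fp, b.n_timepoints))
        series.append(data.astype(np.float32))
    if out_dir is not None:
        import nibabel as nib

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s, data in enumerate(series):
            img = nib.Nifti1Image(data, layout.grid.affine)
            nib.save(img, str(out / f"normative-{s + 1:03d}.nii.gz"))
    return series


@dataclasses.dataclass
class SimulatedConnectome:
    layout: ConnectomeLayout
    patient_seeds: list[LesionMask]
    bold_series: list[np.ndarray]
    truth: dict


def simulate_connectome(
    cfg: SimulationConfig, cohort: SimulatedCohort | None = None
) -> SimulatedConnectome:
    """Patient seed masks on the BOLD grid plus the normative series.

    Patient laterality and posterior extent are shared with the tabular
    cohort (the same subjects seed the connectome analysis); each bold-grid
    seed is a contiguous slice run from the head of the footprint to the
    subject's posterior extent, with a jittered in-plane sub-block.
    """
    lesions = simulate_lesions(cfg)  # same stage stream: geometry matches cohort
    layout = connectome_layout(cfg)
    rng = _rng(cfg.seed, 5)
    seeds: list[LesionMask] = []
    depth = cfg.bold.seed_window_slices
    for i, (lat, f) in enumerate(zip(lesions.lateralities, lesions.posterior_extent)):
        fp = layout.right_seed if lat == "right" else layout.left_seed
        xs, ys, zs = np.where(fp)
        x0, x1 = xs.min(), xs.max()
        y0, y1 = ys.min(), ys.max()
        z0, z1 = zs.min(), zs.max()
        # fixed-size seed: a 2x2 in-plane sub-block over `depth` slices whose
        # posterior end tracks the subject's posterior extent fraction; equal
        # seed sizes keep the idiosyncratic variance share uniform across
        # patients
        b = y0 + int(round(f * (y1 - y0)))
        start = min(max(y0, b - depth + 1), y1 - depth + 1)
        ox = int(rng.integers(0, x1 - x0))
        oz = int(rng.integers(0, z1 - z0))
        data = np.zeros(cfg.bold.shape, dtype=np.uint8)
        data[x0 + ox : x0 + ox + 2, start : start + depth, z0 + oz : z0 + oz + 2] = 1
        seeds.append(
            LesionMask(
                grid=layout.grid.like(data),
                subject_id=f"sub-{i + 1:03d}",
                laterality=lat,
                score=0,
            )
        )
    bold = simulate_normative_bold(cfg, layout)
    truth = {
        "n_right_target_voxels": int(layout.right_targets.sum()),
        "n_left_target_voxels": int(layout.left_targets.sum()),
        "posterior_extent": lesions.posterior_extent.tolist(),
        "lateralities": lesions.lateralities,
    }
    return SimulatedConnectome(layout=layout, patient_seeds=seeds, bold_series=bold, truth=truth)


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------

def write_simulation(cfg: SimulationConfig, out_dir: str | Path, with_bold: bool = True) -> dict:
    """Write masks/, subjects.csv, landmarks.json, truth.json (and normative/).

    Returns a small manifest of what was written.
    """
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cfg)
    for mask, rec in zip(cohort.masks, cohort.records):
        rel = f"masks/{mask.subject_id}.nii.gz"
        write_mask(mask, out / rel)
        rec.mask_path = rel
    write_table(cohort.records, out / "subjects.csv")
    cohort.landmarks.to_json(out / "landmarks.json")
    manifest = {
        "n_subjects": cfg.n_subjects,
        "subjects": "subjects.csv",
        "landmarks": "landmarks.json",
        "masks": [f"masks/{m.subject_id}.nii.gz" for m in cohort.masks],
    }
    truth = dict(cohort.truth)
    if with_bold:
        conn = simulate_connectome(cfg, cohort)
        (out / "seeds_bold").mkdir(exist_ok=True)
        for seed in conn.patient_seeds:
            write_mask(seed, out / "seeds_bold" / f"{seed.subject_id}.nii.gz")
        simulate_normative_bold(cfg, conn.layout, rng=_rng(cfg.seed, 4), out_dir=out / "normative")
        write_mask(
            VolumeGrid(conn.layout.right_targets.astype(np.uint8), affine=conn.layout.grid.affine),
            out / "right_targets.nii.gz",
        )
        write_mask(
            VolumeGrid(conn.layout.left_targets.astype(np.uint8), affine=conn.layout.grid.affine),
            out / "left_targets.nii.gz",
        )
        truth.update(conn.truth)
        manifest["normative"] = "normative/"
        manifest["seeds_bold"] = "seeds_bold/"
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    manifest["truth"] = "truth.json"
    return manifest
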