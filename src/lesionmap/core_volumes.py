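"""Volume data model, NIfTI and CSV I/O, Dice overlap, and rostro-caudal coding.

All voxel-wise analyses in this package operate on binary hippocampal lesion
masks that live on a single common grid (the "standard space" of the study).
This module provides that grid (:class:`VolumeGrid`), the mask and subject
record types, overlap and volume measures, and the head/body/tail coding of
a mask along the anterior-posterior axis of the hippocampus.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    EmptyMaskError,
    FormatError,
    LandmarkError,
    SchemaError,
    ValidationError,
)

#: absolute tolerance used when deciding whether two grids are aligned;
#: distinguishes a real grid mismatch from float32 round-trip noise
ALIGN_ATOL = 1e-6

LATERALITIES = ("left", "right")
ENGEL_CLASSES = ("1", "2", "3", "4", "unknown")


@dataclasses.dataclass
class VolumeGrid:
    """A 3D scalar lattice with a voxel-index -> world-mm affine.

    Parameters
    ----------
    data:
        3D array of scalars. Binary masks use {0, 1}.
    affine:
        4x4 voxel-to-world map. If omitted, a diagonal affine built from
        ``spacing`` (default 1 mm isotropic) is used.
    spacing:
        Voxel edge lengths in mm, only consulted when ``affine`` is None.
    """

    data: np.ndarray
    affine: np.ndarray | None = None
    spacing: dataclasses.InitVar[Sequence[float] | None] = None

    def __post_init__(self, spacing):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValidationError(f"volume shape entries must be >= 1, got {self.data.shape}")
        if self.affine is None:
            sp = (1.0, 1.0, 1.0) if spacing is None else tuple(float(s) for s in spacing)
            self.affine = np.diag((*sp, 1.0))
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if np.any(self.voxel_spacing <= 0):
            raise ValidationError(f"voxel spacing must be positive, got {self.voxel_spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing))

    def aligned(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_spacing, other.voxel_spacing, atol=ALIGN_ATOL)
            and np.allclose(self.affine, other.affine, atol=ALIGN_ATOL)
        )

    def check_aligned(self, other: "VolumeGrid") -> None:
        """Raise :class:`AlignmentError` naming the first mismatching attribute."""
        if self.shape != other.shape:
            raise AlignmentError(f"shape mismatch: {self.shape} vs {other.shape}")
        if not np.allclose(self.voxel_spacing, other.voxel_spacing, atol=ALIGN_ATOL):
            raise AlignmentError(
                f"spacing mismatch: {self.voxel_spacing} vs {other.voxel_spacing}"
            )
        if not np.allclose(self.affine, other.affine, atol=ALIGN_ATOL):
            raise AlignmentError("affine mismatch")

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid with the same geometry holding ``data``."""
        return VolumeGrid(np.asarray(data), affine=self.affine.copy())


@dataclasses.dataclass
class LesionMask:
    """A binary lesion mask plus subject metadata.

    The mask is the unit of every voxel-wise analysis: Dice agreement,
    frequency/average severity maps, and connectivity seeding.
    """

    grid: VolumeGrid
    subject_id: str
    laterality: str = "left"
    score: int = 0  # 0-4 seizure-freedom score; lower = worse prognosis

    def __post_init__(self):
        data = np.asarray(self.grid.data)
        values = np.unique(data)
        if not np.all(np.isin(values, (0, 1))):
            raise ValidationError(
                f"mask data must be strictly binary, found values {values[:5]}"
            )
        if not data.any():
            raise EmptyMaskError(f"mask for subject {self.subject_id!r} has no nonzero voxel")
        if self.laterality not in LATERALITIES:
            raise ValidationError(f"laterality must be one of {LATERALITIES}, got {self.laterality!r}")
        if self.score not in (0, 1, 2, 3, 4):
            raise ValidationError(f"score must be an integer in 0..4, got {self.score!r}")

    @property
    def indicator(self) -> np.ndarray:
        return self.grid.data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.indicator.sum())


@dataclasses.dataclass
class SubjectRecord:
    """Per-subject covariates used by the severity and thickness analyses."""

    subject_id: str
    laterality: str
    score: int
    age_at_onset: float
    age_at_surgery: float
    mean_thickness: float
    engel_class: str = "unknown"
    sex: str | None = None
    lesion_volume: float | None = None  # cc
    has_head: bool | None = None
    has_body: bool | None = None
    has_tail: bool | None = None
    mask_path: str | None = None

    def __post_init__(self):
        if self.laterality not in LATERALITIES:
            raise ValidationError(
                f"{self.subject_id}: laterality must be one of {LATERALITIES}"
            )
        if int(self.score) != self.score or not 0 <= self.score <= 4:
            raise ValidationError(f"{self.subject_id}: score must be an integer in 0..4")
        self.score = int(self.score)
        if self.age_at_surgery < self.age_at_onset:
            raise ValidationError(
                f"{self.subject_id}: age_at_surgery ({self.age_at_surgery}) < "
                f"age_at_onset ({self.age_at_onset})"
            )
        self.engel_class = str(self.engel_class)
        if self.engel_class not in ENGEL_CLASSES:
            raise ValidationError(
                f"{self.subject_id}: engel_class must be one of {ENGEL_CLASSES}"
            )
        if self.lesion_volume is not None and not self.lesion_volume > 0:
            raise ValidationError(f"{self.subject_id}: lesion_volume must be > 0")

    @property
    def duration(self) -> float:
        """Disease duration in years (age at surgery minus age at onset)."""
        return self.age_at_surgery - self.age_at_onset


@dataclasses.dataclass
class SubfieldLandmarks:
    """Slice-index encoding of the manual head/body/tail landmarks.

    The head-body boundary is the first body slice and the body-tail boundary
    the first tail slice: a boundary slice always belongs to the more
    posterior segment, so the three slice ranges are half-open and no slice
    is double-counted. ``anterior_direction`` states whether the anterior end
    of the hippocampus lies toward increasing or decreasing slice indices.
    """

    axis: int
    head_body_boundary: int
    body_tail_boundary: int
    anterior_direction: str = "decreasing"

    def __post_init__(self):
        if self.axis not in (0, 1, 2):
            raise LandmarkError(f"axis must be 0, 1 or 2, got {self.axis}")
        if self.anterior_direction not in ("increasing", "decreasing"):
            raise LandmarkError("anterior_direction must be 'increasing' or 'decreasing'")
        hbb, btb = self.head_body_boundary, self.body_tail_boundary
        if self.anterior_direction == "decreasing":
            # anterior = low index; posterior = high index
            if not hbb < btb:
                raise LandmarkError(
                    "head_body_boundary must be strictly anterior to body_tail_boundary"
                )
        else:
            if not hbb > btb:
                raise LandmarkError(
                    "head_body_boundary must be strictly anterior to body_tail_boundary"
                )

    def segment_of_slices(self, n_slices: int) -> np.ndarray:
        """Array of length ``n_slices`` with values 'head'/'body'/'tail'."""
        for b in (self.head_body_boundary, self.body_tail_boundary):
            if not 0 <= b < n_slices:
                raise LandmarkError(f"boundary slice {b} outside grid of {n_slices} slices")
        idx = np.arange(n_slices)
        seg = np.empty(n_slices, dtype=object)
        if self.anterior_direction == "decreasing":
            seg[idx < self.head_body_boundary] = "head"
            seg[(idx >= self.head_body_boundary) & (idx < self.body_tail_boundary)] = "body"
            seg[idx >= self.body_tail_boundary] = "tail"
        else:
            seg[idx > self.head_body_boundary] = "head"
            seg[(idx <= self.head_body_boundary) & (idx > self.body_tail_boundary)] = "body"
            seg[idx <= self.body_tail_boundary] = "tail"
        return seg

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SubfieldLandmarks":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3D NIfTI-1 file into a :class:`VolumeGrid`."""
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return VolumeGrid(data, affine=np.asarray(img.affine))


def read_mask(
    path: str | Path,
    reference: VolumeGrid | None = None,
    *,
    subject_id: str | None = None,
    laterality: str = "left",
    score: int = 0,
) -> LesionMask:
    """Read a binary lesion mask, binarizing any float input at > 0.5.

    The > 0.5 rule makes the reader robust to float round-trips of 0/1 data
    while mapping genuinely probabilistic inputs to their majority label.
    """
    grid = read_volume(path)
    if reference is not None:
        grid.check_aligned(reference)
    binary = (np.nan_to_num(np.asarray(grid.data, dtype=float)) > 0.5).astype(np.uint8)
    if not binary.any():
        raise EmptyMaskError(f"{path}: mask is empty after binarization")
    sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
    return LesionMask(grid.like(binary), subject_id=sid, laterality=laterality, score=score)


def write_map(grid: VolumeGrid, path: str | Path) -> None:
    """Write a scalar map as float32 NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def write_mask(mask: LesionMask | VolumeGrid, path: str | Path) -> None:
    """Write a binary mask as uint8 NIfTI-1."""
    grid = mask.grid if isinstance(mask, LesionMask) else mask
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=np.uint8), grid.affine)
    nib.save(img, str(path))


def dice(x: LesionMask, y: LesionMask) -> float:
    """Sorensen-Dice overlap 2|X n Y| / (|X| + |Y|) of two aligned masks."""
    x.grid.check_aligned(y.grid)
    a, b = x.indicator, y.indicator
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise EmptyMaskError("Dice undefined: both masks are empty")
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def lesion_volume_cc(m: LesionMask) -> float:
    """Lesion volume in cc: nonzero voxel count x voxel volume (mm^3) / 1000."""
    return m.n_voxels * m.grid.voxel_volume_mm3 / 1000.0


def assign_subfields(m: LesionMask, landmarks: SubfieldLandmarks) -> tuple[bool, bool, bool]:
    """Head/body/tail involvement flags of a mask.

    A flag is true iff the mask has at least one nonzero voxel in a slice of
    the corresponding range along the anterior-posterior axis.
    """
    n_slices = m.grid.shape[landmarks.axis]
    seg = landmarks.segment_of_slices(n_slices)
    other_axes = tuple(a for a in range(3) if a != landmarks.axis)
    touched = m.indicator.any(axis=other_axes)
    return (
        bool(touched[seg == "head"].any()),
        bool(touched[seg == "body"].any()),
        bool(touched[seg == "tail"].any()),
    )


# ---------------------------------------------------------------------------
# subject table I/O
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = (
    "subject_id",
    "laterality",
    "score",
    "age_at_onset",
    "age_at_surgery",
    "mean_thickness",
)
OPTIONAL_COLUMNS = (
    "engel_class",
    "sex",
    "lesion_volume",
    "has_head",
    "has_body",
    "has_tail",
    "mask_path",
)

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _parse_bool(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    try:
        return _BOOL_MAP[str(v).strip().lower()]
    except KeyError:
        raise ValidationError(f"cannot interpret {v!r} as a boolean flag") from None


def read_table(path: str | Path) -> list[SubjectRecord]:
    """Read a subject table CSV, validating the schema and every record."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"subject table {path} is missing required columns: {missing}")
    records = []
    for row in df.to_dict("records"):
        kwargs = dict(
            subject_id=str(row["subject_id"]),
            laterality=str(row["laterality"]),
            score=int(row["score"]),
            age_at_onset=float(row["age_at_onset"]),
            age_at_surgery=float(row["age_at_surgery"]),
            mean_thickness=float(row["mean_thickness"]),
        )
        for col in ("engel_class", "sex", "mask_path"):
            if col in df.columns and not pd.isna(row[col]):
                val = row[col]
                if col == "engel_class" and not isinstance(val, str):
                    val = str(int(val)) if float(val) == int(val) else str(val)
                kwargs[col] = str(val)
        if "lesion_volume" in df.columns and not pd.isna(row["lesion_volume"]):
            kwargs["lesion_volume"] = float(row["lesion_volume"])
        for col in ("has_head", "has_body", "has_tail"):
            if col in df.columns:
                kwargs[col] = _parse_bool(row[col])
        records.append(SubjectRecord(**kwargs))
    return records


def write_table(records: Iterable[SubjectRecord], path: str | Path) -> None:
    """Write subject records to CSV; round-trips losslessly through read_table."""
    rows = []
    for r in records:
        row = dataclasses.asdict(r)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))
    df.to_csv(path, index=False)


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Subject records as a DataFrame with a derived ``duration`` column."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df["duration"] = df["age_at_surgery"] - df["age_at_onset"]
    return df
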