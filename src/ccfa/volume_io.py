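"""Volumetric data model and NIfTI / CSV input-output.

All stages of the pipeline exchange 3-D scalar volumes (FA maps, tract
density maps, probability maps, statistic maps) through the :class:`Volume`
container defined here.  Volumes are assumed to live on one common grid:
registration is upstream of this package, so cross-volume operations are
plain index-aligned arithmetic guarded by :func:`assert_same_grid` — there
is no resampling anywhere.

NIfTI-1 single-file images (``.nii`` / ``.nii.gz``) are the on-disk format,
written as float32; scaling slope/intercept are honoured on read (nibabel's
``get_fdata`` applies them).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: Recognised cohort labels.  ATLAS marks subjects used only for atlas
#: construction; they are excluded from group statistics.
VALID_GROUPS = ("AD", "aMCI", "HC", "ATLAS")

#: Affine entries must agree to this absolute tolerance to count as the
#: same grid.
AFFINE_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Two volumes do not share a shape/affine grid."""


@dataclass
class Volume:
    """A 3-D scalar grid with a voxel-to-world affine.

    Parameters
    ----------
    data:
        3-D array of finite real values (dimensionless FA, probability,
        or a test statistic).
    affine:
        4x4 invertible voxel-to-world transform.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got {self.data.ndim}-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        n_bad = int(np.count_nonzero(~np.isfinite(self.data)))
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """A 3-D mask whose values are exactly 0 or 1."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask data must be 3-D, got {arr.ndim}-D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {uniq[:5]}")
        self.data = arr.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def as_volume(self) -> Volume:
        return Volume(self.data.astype(np.float64), self.affine)


@dataclass
class SubjectRow:
    subject_id: str
    group: str
    fa_path: str


@dataclass
class SubjectManifest:
    """Cohort table: one row per subject (id, group, FA-map path)."""

    rows: list[SubjectRow]

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_id(s): {dup}")
        for r in self.rows:
            if r.group not in VALID_GROUPS:
                raise ValueError(
                    f"subject {r.subject_id!r}: unknown group {r.group!r} "
                    f"(expected one of {VALID_GROUPS})"
                )

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, groups: Iterable[str]) -> "SubjectManifest":
        keep = set(groups)
        return SubjectManifest([r for r in self.rows if r.group in keep])

    def analysis_rows(self) -> list[SubjectRow]:
        """Rows belonging to analysis groups (everything but ATLAS)."""
        return [r for r in self.rows if r.group != "ATLAS"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.subject_id, r.group, r.fa_path) for r in self.rows],
            columns=["subject_id", "group", "fa_path"],
        )


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a single-volume NIfTI-1 image.

    Scaling slope/intercept are applied; the affine is preserved.  4-D
    images and images containing non-finite voxels are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D single-volume image, got shape {data.shape}")
    n_bad = int(np.count_nonzero(~np.isfinite(data)))
    if n_bad:
        raise ValueError(f"{path}: contains {n_bad} non-finite voxel(s)")
    return Volume(data, np.asarray(img.affine))


def write_volume(vol: Volume | BinaryMask, path: str | os.PathLike) -> None:
    """Write a volume as float32 NIfTI-1 (no scaling applied)."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_data_dtype(np.float32)
    nib.save(img, str(path))


def assert_same_grid(vols: Sequence[Volume | BinaryMask], names: Sequence[str] | None = None) -> None:
    """Check that all volumes share one grid (shape and affine).

    Raises :class:`GridMismatchError` naming the first offender.  Affines
    may differ entrywise by at most ``AFFINE_ATOL``.
    """
    if len(vols) == 0:
        raise ValueError("assert_same_grid: empty volume list")
    if names is None:
        names = [f"volume[{i}]" for i in range(len(vols))]
    ref = vols[0]
    for vol, name in zip(vols[1:], names[1:]):
        if vol.shape != ref.shape:
            raise GridMismatchError(
                f"{name}: shape {vol.shape} != reference {names[0]} shape {ref.shape}"
            )
        if not np.allclose(vol.affine, ref.affine, atol=AFFINE_ATOL, rtol=0.0):
            raise GridMismatchError(
                f"{name}: affine differs from reference {names[0]} by more than {AFFINE_ATOL}"
            )


def read_manifest(path: str | os.PathLike, check_paths: bool = True) -> SubjectManifest:
    """Load a cohort manifest CSV with columns subject_id, group, fa_path.

    Relative fa_path entries are resolved against the CSV's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"subject_id", "group", "fa_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing column(s) {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        raw = "" if pd.isna(rec.fa_path) else str(rec.fa_path)
        if raw:
            fa = Path(raw)
            if not fa.is_absolute():
                fa = path.parent / fa
            raw = str(fa)
        if check_paths and (not raw or not Path(raw).exists()):
            raise FileNotFoundError(
                f"{path}: fa_path for subject {rec.subject_id!r} not found: {raw or '<empty>'}"
            )
        rows.append(SubjectRow(rec.subject_id, rec.group, raw))
    return SubjectManifest(rows)


def write_manifest(manifest: SubjectManifest, path: str | os.PathLike) -> None:
    manifest.to_frame().to_csv(path, index=False)
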