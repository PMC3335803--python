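"""Probabilistic 8-portion corpus-callosum atlas construction.

Per-subject tract density maps (already on one grid) are binarised and
averaged separately for each CC portion, giving per-voxel membership
probabilities; each probability map is then thresholded so that values
below the retention threshold tau (default 0.90) become zero while values
at or above tau keep their original probability.  A voxel may survive in
more than one portion; portions are treated independently downstream.

The boundary case v == tau is retained (>= rule): with n atlas subjects
the attainable probabilities are multiples of 1/n, and keeping ties makes
the behaviour predictable for any n where tau itself is attainable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .phantom import PORTION_IDS
from .volume_io import (
    BinaryMask,
    Volume,
    assert_same_grid,
    read_volume,
    write_volume,
)

DEFAULT_TAU = 0.90


class AtlasConstructionError(RuntimeError):
    """A portion's thresholded probability map is empty."""


@dataclass
class ProbabilisticAtlas:
    """Eight thresholded portion probability maps on one grid.

    Every stored value is 0 or in [tau, 1]; each portion retains at
    least one voxel.
    """

    portions: dict[str, Volume]
    tau: float
    n_subjects: int

    def __post_init__(self) -> None:
        if set(self.portions) != set(PORTION_IDS):
            raise ValueError(
                f"atlas must contain exactly the portions {PORTION_IDS}, "
                f"got {sorted(self.portions)}"
            )
        assert_same_grid(list(self.portions.values()), list(self.portions))
        for pid, vol in self.portions.items():
            vals = vol.data[vol.data > 0]
            if vals.size == 0:
                raise AtlasConstructionError(
                    f"portion {pid}: no voxel at or above tau={self.tau}"
                )
            if np.any(vals < self.tau - 1e-12) or np.any(vals > 1 + 1e-12):
                raise ValueError(f"portion {pid}: values outside {{0}} U [tau, 1]")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return next(iter(self.portions.values())).shape

    @property
    def affine(self) -> np.ndarray:
        return next(iter(self.portions.values())).affine

    def support(self, portion_id: str) -> np.ndarray:
        """Boolean array: voxels with positive membership probability."""
        return self.portions[portion_id].data > 0

    def union_mask(self) -> BinaryMask:
        m = np.zeros(self.grid_shape, dtype=np.uint8)
        for pid in PORTION_IDS:
            m[self.support(pid)] = 1
        return BinaryMask(m, self.affine)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pid, vol in self.portions.items():
            write_volume(vol, out_dir / f"prob_{pid}.nii.gz")
        meta = {"tau": self.tau, "n_subjects": self.n_subjects, "portions": list(PORTION_IDS)}
        (out_dir / "atlas.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, atlas_dir: str | Path) -> "ProbabilisticAtlas":
        atlas_dir = Path(atlas_dir)
        meta = json.loads((atlas_dir / "atlas.json").read_text())
        portions = {
            pid: read_volume(atlas_dir / f"prob_{pid}.nii.gz") for pid in meta["portions"]
        }
        return cls(portions, float(meta["tau"]), int(meta["n_subjects"]))


def binarize_density(density: Volume) -> BinaryMask:
    """Binarise a tract density map: 1 where density > 0."""
    if np.any(density.data < 0):
        raise ValueError("density map contains negative values")
    return BinaryMask((density.data > 0).astype(np.uint8), density.affine)


def build_probability_map(masks: list[BinaryMask]) -> Volume:
    """Voxelwise fraction of subjects whose binary mask covers the voxel."""
    if len(masks) < 2:
        raise ValueError("need at least 2 masks to average")
    assert_same_grid(masks)
    stack = np.stack([m.data for m in masks]).astype(np.float64)
    return Volume(stack.mean(axis=0), masks[0].affine)


def threshold_probability_map(prob: Volume, tau: float = DEFAULT_TAU) -> Volume:
    """Zero probabilities below tau; values >= tau keep their original value."""
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    if np.any(prob.data < 0) or np.any(prob.data > 1):
        raise ValueError("probability map values must lie in [0, 1]")
    out = np.where(prob.data >= tau, prob.data, 0.0)
    return Volume(out, prob.affine)


def build_atlas(
    subject_maps: list[dict[str, BinaryMask]], tau: float = DEFAULT_TAU
) -> ProbabilisticAtlas:
    """Average and threshold per-subject portion masks into an atlas.

    ``subject_maps`` holds one dict per subject mapping portion id to its
    binary density mask; all 8 portions must be present for every
    subject.  Raises :class:`AtlasConstructionError` naming any portion
    whose thresholded map is empty.
    """
    for i, maps in enumerate(subject_maps):
        missing = set(PORTION_IDS) - set(maps)
        if missing:
            raise ValueError(f"subject[{i}] missing portion(s) {sorted(missing)}")
    portions: dict[str, Volume] = {}
    for pid in PORTION_IDS:
        prob = build_probability_map([maps[pid] for maps in subject_maps])
        thresholded = threshold_probability_map(prob, tau)
        if not np.any(thresholded.data > 0):
            raise AtlasConstructionError(
                f"portion {pid}: no voxel reaches probability tau={tau} "
                f"across {len(subject_maps)} subjects"
            )
        portions[pid] = thresholded
    return ProbabilisticAtlas(portions, tau, len(subject_maps))
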