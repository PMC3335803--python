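"""Synthetic cohort generator: pre-registered FA phantoms with callosal tracts.

The generator emulates the data situation downstream of registration in a
corpus-callosum (CC) FA study: every subject lives on one common grid, the
CC is subdivided into eight labelled portions (CC1 orbital frontal ...
CC7 occipital, with the temporal section split into CC6L/CC6R), and two
kinds of per-subject images exist:

* binary tract density maps per portion (stand-ins for binarised
  streamline density maps), equal to the portion geometry with boundary
  voxels dropped at a small jitter probability — imitating the residual
  inter-subject variability that survives registration;
* scalar FA volumes, where each subject first draws a portion-level mean
  FA from a group-specific Normal(mean, between-subject SD) and then each
  tract voxel adds small within-map Gaussian noise; non-tract background
  sits strictly below the 0.2 FA rejection threshold.

The default group distribution parameters are the published per-portion
mean (SD) FA values for mild Alzheimer's disease (AD, n=37), amnestic MCI
(aMCI, n=19) and elderly healthy controls (HC, n=20); they make the
phantom cohorts statistically comparable to the study population the
analysis is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .volume_io import (
    BinaryMask,
    SubjectManifest,
    SubjectRow,
    Volume,
    write_manifest,
    write_volume,
)

#: Canonical portion labels, anterior to posterior, temporal split L/R.
PORTION_IDS = ("CC1", "CC2", "CC3", "CC4", "CC5", "CC6L", "CC6R", "CC7")

#: Published per-portion mean FA / between-subject SD per group.
GROUP_FA_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "AD": {
        "CC1": (0.42, 0.03), "CC2": (0.49, 0.04), "CC3": (0.44, 0.03),
        "CC4": (0.44, 0.03), "CC5": (0.53, 0.03), "CC6L": (0.68, 0.04),
        "CC6R": (0.59, 0.04), "CC7": (0.54, 0.04),
    },
    "aMCI": {
        "CC1": (0.44, 0.03), "CC2": (0.52, 0.04), "CC3": (0.46, 0.03),
        "CC4": (0.44, 0.04), "CC5": (0.53, 0.05), "CC6L": (0.69, 0.05),
        "CC6R": (0.61, 0.04), "CC7": (0.55, 0.04),
    },
    "HC": {
        "CC1": (0.47, 0.02), "CC2": (0.55, 0.02), "CC3": (0.49, 0.02),
        "CC4": (0.48, 0.03), "CC5": (0.58, 0.02), "CC6L": (0.73, 0.01),
        "CC6R": (0.63, 0.02), "CC7": (0.60, 0.02),
    },
}

#: Published group sizes of the study cohorts.
GROUP_SIZES = {"AD": 37, "aMCI": 19, "HC": 20}

#: Number of healthy subjects used for atlas construction in the study.
N_ATLAS_SUBJECTS = 25


@dataclass(frozen=True)
class PortionGeometry:
    """One CC portion: a label and its voxel set on the common grid."""

    portion_id: str
    voxels: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if self.portion_id not in PORTION_IDS:
            raise ValueError(f"unknown portion_id {self.portion_id!r}")
        if len(self.voxels) == 0:
            raise ValueError(f"{self.portion_id}: empty voxel set")

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=np.uint8)
        idx = np.asarray(self.voxels)
        m[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
        return m


def _slab(x0, x1, y0, y1, z0, z1):
    return tuple(
        (int(x), int(y), int(z))
        for x in range(x0, x1)
        for y in range(y0, y1)
        for z in range(z0, z1)
    )


def default_geometry(grid_shape: tuple[int, int, int] = (32, 32, 16)) -> list[PortionGeometry]:
    """Stylised 8-portion CC layout on an axis-aligned grid.

    Six midline slabs run anterior (low y) to posterior (high y) in the
    order CC1, CC2, CC3, CC4, CC5, CC7; the temporal portions CC6L/CC6R
    are lateral blocks flanking the midline at the level of CC4.  All
    eight portions are pairwise disjoint and contain at least 27 voxels.
    """
    nx, ny, nz = grid_shape
    if nx < 16 or ny < 16 or nz < 8:
        raise ValueError(f"grid {grid_shape} too small; need at least 16x16x8")
    wx = max(4, nx // 8)          # midline band width (x)
    wz = max(4, nz // 4)          # axial band width (z)
    xc, zc = nx // 2, nz // 2
    x0, x1 = xc - wx // 2, xc - wx // 2 + wx
    z0, z1 = zc - wz // 2, zc - wz // 2 + wz
    ly = (ny - 2) // 6            # slab length along y
    midline_order = ("CC1", "CC2", "CC3", "CC4", "CC5", "CC7")
    portions: dict[str, PortionGeometry] = {}
    for i, pid in enumerate(midline_order):
        y0 = 1 + i * ly
        portions[pid] = PortionGeometry(pid, _slab(x0, x1, y0, y0 + ly, z0, z1))
    # lateral temporal blocks at the y-level of CC4, one voxel clear of
    # the midline band on each side
    y0 = 1 + 3 * ly
    lx0 = x0 - 1 - wx
    rx0 = x1 + 1
    if lx0 < 0 or rx0 + wx > nx:
        raise ValueError(f"grid {grid_shape} too narrow for lateral portions")
    portions["CC6L"] = PortionGeometry("CC6L", _slab(lx0, lx0 + wx, y0, y0 + ly, z0, z1))
    portions["CC6R"] = PortionGeometry("CC6R", _slab(rx0, rx0 + wx, y0, y0 + ly, z0, z1))
    out = [portions[pid] for pid in PORTION_IDS]
    for g in out:
        if len(g.voxels) < 27:
            raise ValueError(f"grid {grid_shape} too small: {g.portion_id} has {len(g.voxels)} voxels")
    return out


@dataclass
class PhantomConfig:
    """Geometry and group FA distribution parameters for the phantom cohort.

    ``fa_params`` maps group -> portion -> (mean, between-subject SD);
    ``within_sd`` is the voxelwise FA noise inside a subject's tract
    (no published value exists for it — it is a free, configurable
    choice); ``background_fa`` sits below the 0.2 rejection threshold so
    that non-tract voxels never enter regional statistics; ``jitter`` is
    the probability that a boundary voxel of a portion is missing from a
    subject's density map.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    geometry: list[PortionGeometry] = field(default_factory=list)
    fa_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(p) for g, p in GROUP_FA_PARAMS.items()}
    )
    within_sd: float = 0.01
    background_fa: float = 0.1
    jitter: float = 0.1
    n_atlas_subjects: int = N_ATLAS_SUBJECTS
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)  # type: ignore[assignment]
        if not self.geometry:
            self.geometry = default_geometry(self.grid_shape)
        if not 0.0 <= self.jitter < 0.5:
            raise ValueError(f"jitter must be in [0, 0.5), got {self.jitter}")
        if not self.background_fa < 0.2:
            raise ValueError(f"background FA must stay below 0.2, got {self.background_fa}")
        if self.within_sd < 0:
            raise ValueError("within_sd must be >= 0")
        for g, portions in self.fa_params.items():
            for pid, (mu, sd) in portions.items():
                if not 0.0 < mu < 1.0:
                    raise ValueError(f"{g}/{pid}: FA mean {mu} outside (0,1)")
                if sd < 0:
                    raise ValueError(f"{g}/{pid}: negative SD {sd}")
        # portion disjointness
        seen: set[tuple[int, int, int]] = set()
        for geom in self.geometry:
            overlap = seen.intersection(geom.voxels)
            if overlap:
                raise ValueError(f"portion {geom.portion_id} overlaps a previous portion")
            seen.update(geom.voxels)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "fa_params" in raw:
            raw["fa_params"] = {
                g: {p: tuple(v) for p, v in portions.items()}
                for g, portions in raw["fa_params"].items()
            }
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        raw.pop("geometry", None)  # geometry always derived from grid_shape
        return cls(**raw)


def boundary_voxels(geom: PortionGeometry, grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean grid of geometry voxels with >= 1 six-neighbour outside it."""
    m = geom.mask(grid_shape).astype(bool)
    interior = m.copy()
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.zeros_like(m)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if shift == 1:
                src[axis], dst[axis] = slice(0, -1), slice(1, None)
            else:
                src[axis], dst[axis] = slice(1, None), slice(0, -1)
            rolled[tuple(dst)] = m[tuple(src)]
            interior &= rolled
    return m & ~interior


def generate_density_maps(
    cfg: PhantomConfig, n_subjects: int, seed: int
) -> list[dict[str, BinaryMask]]:
    """Per-subject, per-portion binary tract density maps.

    Each subject's mask equals the portion geometry with boundary voxels
    independently dropped with probability ``cfg.jitter``; interior voxels
    are always present.  Deterministic for a given seed.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for density maps")
    rng = np.random.default_rng(seed)
    base = {g.portion_id: g.mask(cfg.grid_shape) for g in cfg.geometry}
    bound = {g.portion_id: boundary_voxels(g, cfg.grid_shape) for g in cfg.geometry}
    subjects = []
    for _ in range(n_subjects):
        maps = {}
        for pid in PORTION_IDS:
            m = base[pid].copy()
            b = bound[pid]
            drop = rng.random(int(b.sum())) < cfg.jitter
            coords = np.argwhere(b)
            m[tuple(coords[drop].T)] = 0
            maps[pid] = BinaryMask(m)
        subjects.append(maps)
    return subjects


def generate_fa_cohort(
    cfg: PhantomConfig, group_sizes: dict[str, int], seed: int
) -> tuple[list[Volume], SubjectManifest]:
    """Generate per-subject FA volumes and a matching manifest.

    For each subject a regional mean FA is drawn per portion from
    Normal(group mean, between-subject SD); every tract voxel then gets
    that mean plus Normal(0, within_sd) noise, clipped to [0.01, 0.99].
    Background voxels get ``background_fa`` plus the same noise, clipped
    to [0.01, 0.199] so they always fall below the 0.2 rejection
    threshold.  Manifest fa_path fields are empty until written to disk
    (see :func:`write_cohort`).
    """
    for g in group_sizes:
        if g not in cfg.fa_params:
            raise ValueError(f"unknown group label {g!r}; have {sorted(cfg.fa_params)}")
    rng = np.random.default_rng(seed)
    masks = {g.portion_id: g.mask(cfg.grid_shape).astype(bool) for g in cfg.geometry}
    volumes: list[Volume] = []
    rows: list[SubjectRow] = []
    for group in sorted(group_sizes):
        params = cfg.fa_params[group]
        for i in range(group_sizes[group]):
            fa = np.full(cfg.grid_shape, cfg.background_fa, dtype=np.float64)
            for pid in PORTION_IDS:
                mu, sd = params[pid]
                subj_mean = rng.normal(mu, sd)
                fa[masks[pid]] = subj_mean
            fa += rng.normal(0.0, cfg.within_sd, size=cfg.grid_shape)
            tract = np.zeros(cfg.grid_shape, dtype=bool)
            for pid in PORTION_IDS:
                tract |= masks[pid]
            fa[tract] = np.clip(fa[tract], 0.01, 0.99)
            fa[~tract] = np.clip(fa[~tract], 0.01, 0.199)
            volumes.append(Volume(fa))
            rows.append(SubjectRow(f"{group}_{i + 1:03d}", group, ""))
    return volumes, SubjectManifest(rows)


def generate_atlas_density_cohort(
    cfg: PhantomConfig, seed: int
) -> tuple[list[dict[str, BinaryMask]], SubjectManifest]:
    """Density maps plus an ATLAS-group manifest for atlas construction."""
    maps = generate_density_maps(cfg, cfg.n_atlas_subjects, seed)
    rows = [SubjectRow(f"ATLAS_{i + 1:03d}", "ATLAS", "") for i in range(len(maps))]
    return maps, SubjectManifest(rows)


def write_cohort(
    volumes: list[Volume],
    manifest: SubjectManifest,
    out_dir: str | Path,
) -> SubjectManifest:
    """Write FA volumes as NIfTI and return a manifest with resolved paths."""
    out_dir = Path(out_dir).resolve()
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    rel_rows = []
    for vol, row in zip(volumes, manifest):
        name = f"{row.subject_id}_fa.nii.gz"
        write_volume(vol, out_dir / name)
        rows.append(SubjectRow(row.subject_id, row.group, str(out_dir / name)))
        rel_rows.append(SubjectRow(row.subject_id, row.group, name))
    # the CSV carries paths relative to its own directory, so the cohort
    # folder stays relocatable
    write_manifest(SubjectManifest(rel_rows), out_dir / "manifest.csv")
    return SubjectManifest(rows)


def write_density_maps(
    subject_maps: list[dict[str, BinaryMask]],
    manifest: SubjectManifest,
    out_dir: str | Path,
) -> None:
    """Write per-subject per-portion density masks as NIfTI files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for maps, row in zip(subject_maps, manifest):
        for pid, mask in maps.items():
            write_volume(mask, out_dir / f"{row.subject_id}_{pid}_density.nii.gz")
    write_manifest(manifest, out_dir / "atlas_manifest.csv")
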