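"""End-to-end study orchestration: phantom or user data through both arms.

``run_full_study`` sequences the whole analysis — atlas construction from
density maps, probability-weighted regional FA extraction, the
skeleton-projection arm, and the statistics suites — and writes a results
bundle (CSV/JSON plus NIfTI maps) that is byte-identical for identical
inputs, configuration and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from .atlas import ProbabilisticAtlas, build_atlas
from .phantom import PORTION_IDS, PhantomConfig
from .regional import RegionalFATable, extract_table
from .skeleton import (
    mean_fa_template,
    project_to_skeleton,
    skeleton_regional_fa,
    skeletonize,
)
from .stats import (
    anova_pairwise,
    logistic_detect,
    mask_statmap_by_portion,
    voxelwise_permutation_tfce,
)
from .volume_io import (
    SubjectManifest,
    Volume,
    read_manifest,
    read_volume,
    write_volume,
)

logger = logging.getLogger(__name__)

STUDY_CONTRASTS = (("AD", "HC"), ("aMCI", "HC"), ("AD", "aMCI"))


class StageError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Every tunable of the study flow in one place.

    With ``manifest`` set, FA volumes are read from disk (plus
    ``density_dir`` or ``atlas_dir`` for the atlas); otherwise a phantom
    cohort is generated from ``phantom_cfg`` and ``group_sizes``.
    """

    out_dir: str = "ccfa_results"
    manifest: str | None = None
    density_dir: str | None = None
    atlas_dir: str | None = None
    # analysis constants
    tau: float = 0.90
    fa_min: float = 0.2
    skeleton_threshold: float = 0.2
    max_search: int = 4
    alpha: float = 0.05
    n_perm: int = 5000
    # seeds
    phantom_seed: int = 0
    split_seed: int = 0
    perm_seed: int = 0
    # arms
    atlas_arm: bool = True
    skeleton_arm: bool = True
    voxelwise_arm: bool = False
    # phantom mode
    phantom_cfg: PhantomConfig = field(default_factory=PhantomConfig)
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(ph.GROUP_SIZES))

    def __post_init__(self) -> None:
        if not 0 < self.tau <= 1:
            raise ValueError(f"tau must be in (0,1], got {self.tau}")
        for name in ("fa_min", "skeleton_threshold", "alpha"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0,1), got {v}")
        if self.max_search < 0:
            raise ValueError("max_search must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "phantom_cfg" in raw:
            raw["phantom_cfg"] = PhantomConfig(**raw["phantom_cfg"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom_cfg"] = {
            "grid_shape": list(self.phantom_cfg.grid_shape),
            "within_sd": self.phantom_cfg.within_sd,
            "background_fa": self.phantom_cfg.background_fa,
            "jitter": self.phantom_cfg.jitter,
            "n_atlas_subjects": self.phantom_cfg.n_atlas_subjects,
        }
        return d


def _stage(name: str):
    """Log wall time per stage and re-raise failures with the stage name."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: FAILED after %.1fs: %s", name, dt, exc)
                raise StageError(f"stage {name}: {exc}") from exc
            logger.info("stage %s: done in %.1fs", name, dt)
            return False

    return _Ctx()


def _provenance_hash(volumes: dict[str, Volume]) -> str:
    h = hashlib.sha256()
    for sid in sorted(volumes):
        h.update(sid.encode())
        h.update(np.ascontiguousarray(volumes[sid].data).tobytes())
    return h.hexdigest()


def _load_density_maps(manifest: SubjectManifest, density_dir: Path):
    subject_maps = []
    for row in manifest:
        if row.group != "ATLAS":
            continue
        maps = {}
        for pid in PORTION_IDS:
            p = density_dir / f"{row.subject_id}_{pid}_density.nii.gz"
            if not p.exists():
                p = density_dir / f"{row.subject_id}_{pid}_density.nii"
            from .atlas import binarize_density

            maps[pid] = binarize_density(read_volume(p))
        subject_maps.append(maps)
    return subject_maps


def run_full_study(cfg: RunConfig) -> dict[str, str]:
    """Run the configured arms end to end; returns output name -> path."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    # ---- inputs -----------------------------------------------------------
    with _stage("inputs"):
        if cfg.manifest is not None:
            manifest = read_manifest(cfg.manifest)
            volumes = {r.subject_id: read_volume(r.fa_path) for r in manifest.analysis_rows()}
        else:
            fa_vols, manifest = ph.generate_fa_cohort(
                cfg.phantom_cfg, cfg.group_sizes, cfg.phantom_seed
            )
            volumes = {r.subject_id: v for r, v in zip(manifest, fa_vols)}
        logger.info("inputs: %d analysis subjects", len(volumes))

    # ---- atlas ------------------------------------------------------------
    with _stage("atlas"):
        if cfg.atlas_dir is not None:
            atlas = ProbabilisticAtlas.load(cfg.atlas_dir)
        elif cfg.manifest is not None and cfg.density_dir is not None:
            subject_maps = _load_density_maps(manifest, Path(cfg.density_dir))
            atlas = build_atlas(subject_maps, cfg.tau)
        elif cfg.manifest is None:
            subject_maps, _ = ph.generate_atlas_density_cohort(
                cfg.phantom_cfg, cfg.phantom_seed + 1
            )
            atlas = build_atlas(subject_maps, cfg.tau)
        else:
            raise ValueError("need density_dir or atlas_dir when a manifest is given")
        atlas.save(out_dir / "atlas")
        outputs["atlas"] = str(out_dir / "atlas")

    contrasts = [
        c
        for c in STUDY_CONTRASTS
        if all((manifest.to_frame()["group"] == g).sum() >= 5 for g in c)
    ]

    # ---- atlas-based arm --------------------------------------------------
    if cfg.atlas_arm:
        with _stage("atlas_fa_extraction"):
            regional = extract_table(manifest, atlas, cfg.fa_min, volumes=volumes)
            regional.to_csv(out_dir / "regional_fa.csv")
            outputs["regional_fa"] = str(out_dir / "regional_fa.csv")
        with _stage("atlas_stats"):
            _write_stats(regional, contrasts, cfg, out_dir, "atlas", outputs)

    # ---- skeleton arm -----------------------------------------------------
    skel = None
    if cfg.skeleton_arm:
        with _stage("skeleton"):
            analysis_ids = [r.subject_id for r in manifest.analysis_rows()]
            template = mean_fa_template([volumes[s] for s in analysis_ids])
            write_volume(template, out_dir / "mean_fa_template.nii.gz")
            skel = skeletonize(template, cfg.skeleton_threshold)
            write_volume(skel.mask, out_dir / "skeleton_mask.nii.gz")
            rows = []
            for r in manifest.analysis_rows():
                proj = project_to_skeleton(volumes[r.subject_id], skel, cfg.max_search)
                means = skeleton_regional_fa(proj, atlas)
                rows.append({"subject_id": r.subject_id, "group": r.group, **means})
            skeleton_table = RegionalFATable(pd.DataFrame(rows), fa_min=0.0, tau=cfg.tau)
            skeleton_table.to_csv(out_dir / "skeleton_fa.csv")
            outputs["skeleton_fa"] = str(out_dir / "skeleton_fa.csv")
        with _stage("skeleton_stats"):
            _write_stats(skeleton_table, contrasts, cfg, out_dir, "skeleton", outputs)

    # ---- voxelwise arm ----------------------------------------------------
    if cfg.voxelwise_arm:
        with _stage("voxelwise"):
            mask = atlas.union_mask()
            frame = manifest.to_frame()
            for a, b in contrasts:
                ids = frame.loc[frame["group"].isin((a, b)), "subject_id"]
                labs = frame.set_index("subject_id").loc[ids, "group"].tolist()
                vols = [volumes[s] for s in ids]
                # contrast b - a: FA reduction in the affected group shows
                # as a positive statistic for the reference group
                res = voxelwise_permutation_tfce(
                    vols, labs, mask, contrast=(b, a),
                    n_perm=cfg.n_perm, seed=cfg.perm_seed,
                )
                tag = f"{a}_vs_{b}"
                write_volume(res.p_corrected, out_dir / f"voxelwise_pcorr_{tag}.nii.gz")
                counts = mask_statmap_by_portion(res, atlas, cfg.alpha)
                counts.to_csv(out_dir / f"voxelwise_counts_{tag}.csv", index=False)
                outputs[f"voxelwise_{tag}"] = str(out_dir / f"voxelwise_counts_{tag}.csv")

    # ---- run manifest -----------------------------------------------------
    with _stage("run_manifest"):
        run_meta = {
            "config": cfg.to_dict(),
            "contrasts": [list(c) for c in contrasts],
            "n_subjects": len(volumes),
            "input_hash": _provenance_hash(volumes),
            "outputs": outputs,
        }
        (out_dir / "run_manifest.json").write_text(json.dumps(run_meta, indent=2))
        outputs["run_manifest"] = str(out_dir / "run_manifest.json")
    return outputs


def _write_stats(
    table: RegionalFATable,
    contrasts: list[tuple[str, str]],
    cfg: RunConfig,
    out_dir: Path,
    arm: str,
    outputs: dict[str, str],
) -> None:
    if len(table.groups()) >= 2:
        res = anova_pairwise(table, cfg.alpha)
        res.table.to_csv(out_dir / f"anova_{arm}.csv", index=False)
        outputs[f"anova_{arm}"] = str(out_dir / f"anova_{arm}.csv")
    for pos, neg in contrasts:
        cls = logistic_detect(table, (pos, neg), cfg.split_seed)
        payload = dataclasses.asdict(cls)
        payload["contrast"] = list(cls.contrast)
        path = out_dir / f"classify_{arm}_{pos}_vs_{neg}.json"
        path.write_text(json.dumps(payload, indent=2))
        outputs[f"classify_{arm}_{pos}_vs_{neg}"] = str(path)
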