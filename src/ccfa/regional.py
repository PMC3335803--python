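"""Atlas-based probability-weighted regional FA extraction.

For each subject and each CC portion, the regional value is the FA
average over the portion's atlas support, weighted by the voxelwise
membership probability:

    mean_FA = sum_v p(v) * FA(v) / sum_v p(v),   v in S
    S = { v : p(v) > 0  and  FA(v) >= fa_min }

Voxels with FA below ``fa_min`` (default 0.2, the conventional white
matter floor) are rejected before averaging, which protects the regional
estimate from grey-matter and CSF partial-volume contamination at tract
borders; FA exactly equal to fa_min is kept.  Rejections are counted per
subject for diagnostics, and an empty S is an error, never a silent zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ProbabilisticAtlas
from .phantom import PORTION_IDS
from .volume_io import SubjectManifest, Volume, assert_same_grid, read_volume

logger = logging.getLogger(__name__)

DEFAULT_FA_MIN = 0.2


class EmptyRegionError(RuntimeError):
    """No voxel of a portion survives the FA floor for a subject."""


@dataclass
class RegionalFATable:
    """Subjects x portions table of regional mean FA plus extraction metadata.

    ``data`` has columns subject_id, group, the 8 portion ids, and
    ``n_<portion>`` voxel counts.
    """

    data: pd.DataFrame
    fa_min: float = DEFAULT_FA_MIN
    tau: float | None = None

    def __post_init__(self) -> None:
        required = ["subject_id", "group", *PORTION_IDS]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"regional FA table missing column(s) {missing}")
        vals = self.data[list(PORTION_IDS)].to_numpy(dtype=float)
        if np.any(vals < self.fa_min - 1e-12) or np.any(vals > 1 + 1e-12):
            raise ValueError("regional FA values must lie in [fa_min, 1]")

    def group_values(self, portion_id: str, group: str) -> np.ndarray:
        sel = self.data["group"] == group
        return self.data.loc[sel, portion_id].to_numpy(dtype=float)

    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    def group_summary(self) -> pd.DataFrame:
        """Per portion and group: n, across-subject mean and sample SD."""
        records = []
        for pid in PORTION_IDS:
            for group in self.groups():
                vals = self.group_values(pid, group)
                records.append(
                    {
                        "portion": pid,
                        "group": group,
                        "n": len(vals),
                        "mean_fa": float(np.mean(vals)),
                        "sd_fa": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    }
                )
        return pd.DataFrame(records)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, fa_min: float = DEFAULT_FA_MIN, tau: float | None = None
    ) -> "RegionalFATable":
        return cls(pd.read_csv(path), fa_min=fa_min, tau=tau)


def weighted_regional_fa(
    fa: Volume,
    prob: Volume,
    fa_min: float = DEFAULT_FA_MIN,
    context: str = "",
) -> tuple[float, int]:
    """Probability-weighted mean FA over one portion's atlas support.

    Returns (weighted mean, number of contributing voxels).  Voxels with
    positive probability but FA below ``fa_min`` are excluded from both
    numerator and denominator; their count is logged.
    """
    assert_same_grid([fa, prob], ["fa", "prob"])
    support = prob.data > 0
    accepted = support & (fa.data >= fa_min)
    n_rejected = int(support.sum() - accepted.sum())
    if n_rejected:
        logger.debug("%s: rejected %d sub-threshold voxel(s)", context or "region", n_rejected)
    if not np.any(accepted):
        raise EmptyRegionError(
            f"{context or 'region'}: no voxel with FA >= {fa_min} in the portion support"
        )
    w = prob.data[accepted]
    v = fa.data[accepted]
    return float(np.sum(w * v) / np.sum(w)), int(accepted.sum())


def extract_table(
    manifest: SubjectManifest,
    atlas: ProbabilisticAtlas,
    fa_min: float = DEFAULT_FA_MIN,
    volumes: dict[str, Volume] | None = None,
) -> RegionalFATable:
    """Probability-weighted regional FA for every analysis subject.

    FA volumes are loaded from the manifest's fa_path entries unless an
    in-memory ``volumes`` mapping (subject_id -> Volume) is supplied.
    ATLAS-group subjects are skipped.  Deterministic and invariant to
    manifest row order (up to row order of the output).
    """
    records = []
    for row in manifest.analysis_rows():
        if volumes is not None and row.subject_id in volumes:
            fa = volumes[row.subject_id]
        else:
            fa = read_volume(row.fa_path)
        try:
            assert_same_grid(
                [next(iter(atlas.portions.values())), fa], ["atlas", row.subject_id]
            )
        except Exception as exc:
            raise type(exc)(f"subject {row.subject_id}: {exc}") from exc
        rec: dict[str, object] = {"subject_id": row.subject_id, "group": row.group}
        for pid in PORTION_IDS:
            try:
                mean_fa, n_vox = weighted_regional_fa(
                    fa, atlas.portions[pid], fa_min, context=f"{row.subject_id}/{pid}"
                )
            except EmptyRegionError as exc:
                raise EmptyRegionError(
                    f"subject {row.subject_id}, portion {pid}: {exc}"
                ) from exc
            rec[pid] = mean_fa
            rec[f"n_{pid}"] = n_vox
        records.append(rec)
    df = pd.DataFrame(records)
    return RegionalFATable(df, fa_min=fa_min, tau=atlas.tau)
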