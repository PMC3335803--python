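"""Simplified skeleton-projection FA analysis (TBSS-style arm).

The skeleton arm mirrors the standard tract-based spatial statistics
workflow at the fidelity this comparison needs: a group mean-FA template
is reduced to a one-voxel-thick ridge ("skeleton"), each subject's FA is
projected onto the skeleton by searching perpendicular to the local tract
direction for the highest FA, and regional statistics are taken over
skeleton voxels inside each atlas portion.

Skeletonisation here is a ridge detector rather than the packaged
distance-map machinery: the template is smoothed (Gaussian, sigma 1
voxel) and a local tract-perpendicular is estimated at each voxel — the
direction of steepest FA ascent where the gradient is appreciable (it
points at the tract centre), otherwise the eigenvector of the local
Hessian with the most negative eigenvalue (the direction of sharpest FA
fall-off, well defined exactly on the ridge where the gradient
vanishes).  A voxel joins the skeleton iff its template FA reaches the
threshold (default 0.2) and is a local maximum along that perpendicular
(>= both linearly interpolated neighbours at +/-1 voxel — ties are kept,
biasing toward connected skeletons).  Projection takes the
maximum subject FA over integer steps 0..max_search along the +/-
perpendicular with nearest-voxel sampling, as in the published projection
rule.  This reproduces the qualitative behaviour of the reference method
(notably that projected regional means exceed tract-volume means) without
claiming bit-compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .atlas import ProbabilisticAtlas
from .phantom import PORTION_IDS
from .volume_io import BinaryMask, Volume, assert_same_grid

DEFAULT_SKELETON_THRESHOLD = 0.2
DEFAULT_MAX_SEARCH = 4
HESSIAN_SMOOTH_SIGMA = 1.0


class EmptySkeletonError(RuntimeError):
    """No template voxel reaches the skeleton threshold."""


@dataclass
class Skeleton:
    """Binary ridge mask plus the per-voxel tract-perpendicular field."""

    mask: BinaryMask
    perp_dir: np.ndarray  # (nx, ny, nz, 3), unit vectors
    template_id: str = "mean_fa"

    def __post_init__(self) -> None:
        if self.perp_dir.shape != (*self.mask.shape, 3):
            raise ValueError("perp_dir shape must be grid shape + (3,)")
        on = self.mask.data.astype(bool)
        norms = np.linalg.norm(self.perp_dir[on], axis=-1)
        if on.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("perpendicular vectors must be unit-norm on the skeleton")

    @property
    def coords(self) -> np.ndarray:
        """(n_skel, 3) integer voxel indices of skeleton voxels."""
        return np.argwhere(self.mask.data.astype(bool))


@dataclass
class SkeletonProjection:
    """Per-subject FA values defined exactly on the skeleton voxels."""

    skeleton: Skeleton
    values: np.ndarray  # 1-D, aligned with skeleton.coords

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.skeleton.coords),):
            raise ValueError("one projected value per skeleton voxel required")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("projected FA must lie in [0, 1]")

    def to_volume(self, fill: float = 0.0) -> Volume:
        out = np.full(self.skeleton.mask.shape, fill, dtype=np.float64)
        c = self.skeleton.coords
        out[c[:, 0], c[:, 1], c[:, 2]] = self.values
        return Volume(out, self.skeleton.mask.affine)


def save_skeleton(skel: Skeleton, out_dir) -> None:
    """Write a skeleton as mask + three perpendicular-component NIfTIs."""
    from pathlib import Path

    from .volume_io import write_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(skel.mask, out_dir / "skeleton_mask.nii.gz")
    for i, ax in enumerate("xyz"):
        write_volume(
            Volume(skel.perp_dir[..., i], skel.mask.affine),
            out_dir / f"perp_{ax}.nii.gz",
        )


def load_skeleton(skel_dir) -> Skeleton:
    from pathlib import Path

    from .volume_io import read_volume

    skel_dir = Path(skel_dir)
    mask_vol = read_volume(skel_dir / "skeleton_mask.nii.gz")
    mask = BinaryMask(np.rint(mask_vol.data).astype(np.uint8), mask_vol.affine)
    comps = [read_volume(skel_dir / f"perp_{ax}.nii.gz").data for ax in "xyz"]
    perp = np.stack(comps, axis=-1)
    on = mask.data.astype(bool)
    norms = np.linalg.norm(perp[on], axis=-1, keepdims=True)
    perp[on] /= norms  # renormalise float32 round-off
    return Skeleton(mask, perp)


def mean_fa_template(volumes: list[Volume]) -> Volume:
    """Voxelwise mean FA across subjects — the skeletonisation template."""
    if not volumes:
        raise ValueError("no volumes for template")
    assert_same_grid(volumes)
    return Volume(np.mean([v.data for v in volumes], axis=0), volumes[0].affine)


#: Voxels whose smoothed-FA gradient magnitude falls below this fraction
#: of the volume maximum are treated as lying on the ridge itself; there
#: the tract-perpendicular comes from the Hessian instead of the gradient.
GRADIENT_SWITCH_FRACTION = 0.05


def _perp_field(template: np.ndarray, sigma: float) -> np.ndarray:
    """Local tract-perpendicular: the direction of steepest FA ascent
    (toward the tract centre), falling back to the Hessian eigenvector
    with the most negative eigenvalue where the gradient vanishes.

    Off the ridge the smoothed-FA gradient points at the tract centre,
    so a local-maximum test along it rejects flank voxels; on the ridge
    the gradient is ~0 and the principal-curvature direction of the
    smoothed template takes over.  Both directions are invariant under
    monotone affine rescaling of the template (the gradient/Hessian
    scale uniformly and the switch is relative to the volume maximum).
    """
    smoothed = ndimage.gaussian_filter(template, sigma=sigma, mode="nearest")
    grads = np.gradient(smoothed)
    grad = np.stack(grads, axis=-1)
    gmag = np.linalg.norm(grad, axis=-1)
    hess = np.empty((*template.shape, 3, 3))
    for i in range(3):
        gi = np.gradient(grads[i])
        for j in range(3):
            hess[..., i, j] = gi[j]
    hess = 0.5 * (hess + np.swapaxes(hess, -1, -2))
    # eigh returns ascending eigenvalues: index 0 = most negative
    _, vecs = np.linalg.eigh(hess)
    perp = np.ascontiguousarray(vecs[..., :, 0])
    strong = gmag > GRADIENT_SWITCH_FRACTION * gmag.max()
    with np.errstate(invalid="ignore", divide="ignore"):
        gdir = grad / gmag[..., None]
    perp[strong] = gdir[strong]
    return perp


def skeletonize(
    template_fa: Volume,
    threshold: float = DEFAULT_SKELETON_THRESHOLD,
    sigma: float = HESSIAN_SMOOTH_SIGMA,
) -> Skeleton:
    """Extract the FA ridge of a template as a skeleton.

    A voxel is on the skeleton iff its template FA is >= ``threshold``
    and >= both linearly interpolated template values one voxel away
    along +/- the local tract-perpendicular.
    """
    data = template_fa.data
    if np.any(data < 0) or np.any(data > 1):
        raise ValueError("template FA must lie in [0, 1]")
    above = data >= threshold
    if not above.any():
        raise EmptySkeletonError(
            f"no template voxel reaches the skeleton threshold {threshold}"
        )
    perp = _perp_field(data, sigma)
    coords = np.argwhere(above).astype(np.float64)
    dirs = perp[above]
    mask = np.zeros(data.shape, dtype=np.uint8)
    for sign in (1.0, -1.0):
        nb = (coords + sign * dirs).T
        vals = ndimage.map_coordinates(data, nb, order=1, mode="nearest")
        if sign > 0:
            keep = data[above] >= vals
        else:
            keep &= data[above] >= vals
    idx = np.argwhere(above)[keep]
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    if not mask.any():
        raise EmptySkeletonError("skeletonisation removed every suprathreshold voxel")
    return Skeleton(BinaryMask(mask, template_fa.affine), perp)


def project_to_skeleton(
    subject_fa: Volume,
    skel: Skeleton,
    max_search: int = DEFAULT_MAX_SEARCH,
) -> SkeletonProjection:
    """Project a subject's FA onto the skeleton.

    At each skeleton voxel the projected value is the maximum subject FA
    at integer steps 0..max_search along +/- the local perpendicular,
    sampled at the nearest voxel; steps leaving the grid are ignored.
    """
    assert_same_grid([subject_fa, skel.mask], ["subject_fa", "skeleton"])
    coords = skel.coords
    dirs = skel.perp_dir[coords[:, 0], coords[:, 1], coords[:, 2]]
    shape = np.asarray(subject_fa.shape)
    best = subject_fa.data[coords[:, 0], coords[:, 1], coords[:, 2]].copy()
    for step in range(1, max_search + 1):
        for sign in (1.0, -1.0):
            probe = np.rint(coords + sign * step * dirs).astype(int)
            inside = np.all((probe >= 0) & (probe < shape), axis=1)
            vals = np.full(len(coords), -np.inf)
            vals[inside] = subject_fa.data[
                probe[inside, 0], probe[inside, 1], probe[inside, 2]
            ]
            best = np.maximum(best, vals)
    return SkeletonProjection(skel, best)


def skeleton_regional_fa(
    proj: SkeletonProjection, atlas: ProbabilisticAtlas
) -> dict[str, float]:
    """Unweighted mean projected FA per portion over skeleton voxels.

    A portion whose atlas support contains no skeleton voxel is an error.
    """
    assert_same_grid(
        [proj.skeleton.mask, next(iter(atlas.portions.values()))], ["skeleton", "atlas"]
    )
    coords = proj.skeleton.coords
    out: dict[str, float] = {}
    for pid in PORTION_IDS:
        support = atlas.support(pid)
        sel = support[coords[:, 0], coords[:, 1], coords[:, 2]]
        if not sel.any():
            raise EmptySkeletonError(f"portion {pid}: no skeleton voxel in its support")
        out[pid] = float(np.mean(proj.values[sel]))
    return out
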