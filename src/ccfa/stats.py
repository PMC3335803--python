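"""Group statistics: ANOVA with Bonferroni post-hoc, logistic detection,
and voxelwise permutation testing with TFCE correction.

Three analyses operate on the regional FA tables and voxel data:

* per-portion one-way ANOVA across the diagnostic groups with pairwise
  post-hoc t tests using the pooled ANOVA error term, Bonferroni-corrected
  over the pairwise contrasts within each portion (the post-hoc convention
  of mainstream statistics packages);
* binary logistic-regression detection of a clinical group against a
  reference using all 8 portion means, reporting apparent (resubstitution)
  accuracy, sensitivity and specificity plus a stratified 80/20
  cross-validation split;
* voxelwise two-sample t statistics with threshold-free cluster
  enhancement (TFCE) and family-wise-error correction from the permutation
  distribution of the maximum TFCE statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .atlas import ProbabilisticAtlas
from .phantom import PORTION_IDS
from .regional import RegionalFATable
from .volume_io import BinaryMask, Volume, assert_same_grid

DEFAULT_ALPHA = 0.05
DEFAULT_N_PERM = 5000
TFCE_E = 0.5
TFCE_H = 2.0
TFCE_DH = 0.1
LOGISTIC_RIDGE = 1e-6

#: Canonical pairwise contrast order for the three study groups.
CANONICAL_PAIRS = (("AD", "HC"), ("aMCI", "HC"), ("aMCI", "AD"))


# ---------------------------------------------------------------------------
# One-way ANOVA with Bonferroni-corrected pairwise post-hocs
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonResult:
    """Per-portion ANOVA summary: group moments, F, corrected pairwise p."""

    table: pd.DataFrame  # one row per (portion, pair)
    summary: pd.DataFrame  # one row per (portion, group): n, mean, sd
    alpha: float

    def corrected_p(self, portion: str, pair: tuple[str, str]) -> float:
        a, b = pair
        sel = self.table[
            (self.table["portion"] == portion)
            & (self.table["group_a"] == a)
            & (self.table["group_b"] == b)
        ]
        if sel.empty:  # try the reversed orientation
            sel = self.table[
                (self.table["portion"] == portion)
                & (self.table["group_a"] == b)
                & (self.table["group_b"] == a)
            ]
        if sel.empty:
            raise KeyError(f"no contrast {pair} for portion {portion}")
        return float(sel["p_corrected"].iloc[0])

    def significant(self, portion: str, pair: tuple[str, str]) -> bool:
        return self.corrected_p(portion, pair) < self.alpha


def _ordered_pairs(groups: list[str]) -> list[tuple[str, str]]:
    canonical = [p for p in CANONICAL_PAIRS if p[0] in groups and p[1] in groups]
    rest = [
        tuple(sorted(p))
        for p in combinations(sorted(groups), 2)
        if tuple(sorted(p)) not in {tuple(sorted(c)) for c in canonical}
    ]
    return canonical + rest  # type: ignore[return-value]


def anova_pairwise(table: RegionalFATable, alpha: float = DEFAULT_ALPHA) -> GroupComparisonResult:
    """One-way ANOVA per portion with Bonferroni-corrected pairwise t tests.

    The pairwise tests use the pooled within-group mean square from the
    full ANOVA (all groups contribute to the error term, with N - k
    degrees of freedom); corrected p = min(1, m * p) where m is the
    number of pairwise contrasts among the groups present.
    """
    groups = table.groups()
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    pairs = _ordered_pairs(groups)
    m = len(pairs)
    rows = []
    summary_rows = []
    for pid in PORTION_IDS:
        samples = {g: table.group_values(pid, g) for g in groups}
        for g, v in samples.items():
            if len(v) < 2:
                raise ValueError(f"group {g} has fewer than 2 subjects")
            summary_rows.append(
                {"portion": pid, "group": g, "n": len(v),
                 "mean_fa": float(np.mean(v)), "sd_fa": float(np.std(v, ddof=1))}
            )
        n_tot = sum(len(v) for v in samples.values())
        k = len(samples)
        grand = np.mean(np.concatenate(list(samples.values())))
        ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in samples.values())
        ssw = sum(np.sum((v - np.mean(v)) ** 2) for v in samples.values())
        df_b, df_w = k - 1, n_tot - k
        msw = ssw / df_w
        if msw == 0.0:
            f_stat = 0.0 if np.isclose(ssb, 0.0) else np.inf
        else:
            f_stat = (ssb / df_b) / msw
        for a, b in pairs:
            va, vb = samples[a], samples[b]
            diff = np.mean(va) - np.mean(vb)
            if msw == 0.0:
                p_raw = 1.0 if np.isclose(diff, 0.0) else 0.0
            else:
                se = np.sqrt(msw * (1 / len(va) + 1 / len(vb)))
                t = diff / se
                p_raw = 2.0 * sps.t.sf(abs(t), df_w)
            p_corr = min(1.0, m * p_raw)
            rows.append(
                {"portion": pid, "group_a": a, "group_b": b,
                 "mean_diff": float(diff), "F": float(f_stat),
                 "df_between": df_b, "df_within": df_w,
                 "p_raw": float(p_raw), "p_corrected": float(p_corr),
                 "significant": bool(p_corr < alpha)}
            )
    return GroupComparisonResult(pd.DataFrame(rows), pd.DataFrame(summary_rows), alpha)


def anova_f_from_summary(
    ns: list[int], means: list[float], sds: list[float]
) -> tuple[float, float]:
    """One-way ANOVA F and p from per-group (n, mean, sample SD) summaries.

    Closed-form reconstruction: SSW = sum (n_g - 1) sd_g^2 and SSB from
    the group means about the grand mean.  Useful as an independent
    cross-check on :func:`anova_pairwise` and for published summary rows.
    """
    ns_arr = np.asarray(ns, dtype=float)
    means_arr = np.asarray(means, dtype=float)
    sds_arr = np.asarray(sds, dtype=float)
    n_tot = ns_arr.sum()
    k = len(ns_arr)
    grand = np.sum(ns_arr * means_arr) / n_tot
    ssb = np.sum(ns_arr * (means_arr - grand) ** 2)
    ssw = np.sum((ns_arr - 1) * sds_arr**2)
    f = (ssb / (k - 1)) / (ssw / (n_tot - k))
    p = float(sps.f.sf(f, k - 1, n_tot - k))
    return float(f), p


# ---------------------------------------------------------------------------
# Logistic-regression detection
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    """Detection of one clinical group against a reference.

    ``overall``/``sensitivity``/``specificity`` are apparent
    (resubstitution) rates on the full fitting sample; ``cv_selected`` /
    ``cv_unselected`` are the correct-classification fractions on the
    80% training and 20% held-out parts of a stratified seeded split
    (averaged when ``n_splits`` > 1).  Positive = the more-affected group
    (the first element of ``contrast``).
    """

    contrast: tuple[str, str]
    overall: float
    sensitivity: float
    specificity: float
    confusion: dict[str, int]  # tp, fn, tn, fp
    cv_selected: float
    cv_unselected: float
    seed: int
    n_splits: int = 1
    ridge: float = LOGISTIC_RIDGE
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        tp, fn = self.confusion["tp"], self.confusion["fn"]
        tn, fp = self.confusion["tn"], self.confusion["fp"]
        n = tp + fn + tn + fp
        assert np.isclose(self.overall, (tp + tn) / n)
        assert np.isclose(self.sensitivity, tp / (tp + fn))
        assert np.isclose(self.specificity, tn / (tn + fp))


def _fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float) -> LogisticRegression:
    model = LogisticRegression(C=1.0 / ridge, max_iter=5000, solver="lbfgs")
    model.fit(X, y)
    return model


def logistic_detect(
    table: RegionalFATable,
    contrast: tuple[str, str],
    seed: int,
    n_splits: int = 1,
    ridge: float = LOGISTIC_RIDGE,
    cutoff: float = 0.5,
) -> ClassificationResult:
    """Logistic detection of ``contrast[0]`` (positive) vs ``contrast[1]``.

    Fits a binary logistic model on all 8 portion means with a mild ridge
    penalty (to survive complete separation, which is surfaced as a
    warning rather than a failure), classifies at the given probability
    cutoff on the fitting data, and runs ``n_splits`` stratified 80/20
    cross-validation splits seeded from ``seed``.
    """
    pos, neg = contrast
    sub = table.data[table.data["group"].isin(contrast)]
    for g in contrast:
        if (sub["group"] == g).sum() < 5:
            raise ValueError(f"group {g} needs >= 5 subjects for classification")
    X = sub[list(PORTION_IDS)].to_numpy(dtype=float)
    y = (sub["group"] == pos).to_numpy(dtype=int)
    model = _fit_logistic(X, y, ridge)
    prob = model.predict_proba(X)[:, 1]
    pred = (prob >= cutoff).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    if fp == 0 and fn == 0 and np.all((prob > 0.99) | (prob < 0.01)):
        warnings.warn(
            f"complete separation between {pos} and {neg}: "
            "coefficients determined by the ridge penalty",
            stacklevel=2,
        )
    sel_acc, unsel_acc = [], []
    for i in range(n_splits):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=0.2, stratify=y, random_state=(seed + i) % (2**31)
        )
        cv_model = _fit_logistic(X_tr, y_tr, ridge)
        sel_acc.append(float(np.mean((cv_model.predict_proba(X_tr)[:, 1] >= cutoff) == y_tr)))
        unsel_acc.append(float(np.mean((cv_model.predict_proba(X_te)[:, 1] >= cutoff) == y_te)))
    coefs = {pid: float(c) for pid, c in zip(PORTION_IDS, model.coef_[0])}
    coefs["intercept"] = float(model.intercept_[0])
    return ClassificationResult(
        contrast=contrast,
        overall=(tp + tn) / len(y),
        sensitivity=tp / (tp + fn) if (tp + fn) else np.nan,
        specificity=tn / (tn + fp) if (tn + fp) else np.nan,
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        cv_selected=float(np.mean(sel_acc)),
        cv_unselected=float(np.mean(unsel_acc)),
        seed=seed,
        n_splits=n_splits,
        ridge=ridge,
        coefficients=coefs,
    )


# ---------------------------------------------------------------------------
# Voxelwise permutation testing with TFCE
# ---------------------------------------------------------------------------

@dataclass
class VoxelwiseResult:
    """Voxelwise two-sample comparison with TFCE-based FWE correction."""

    stat: Volume
    tfce: Volume
    p_corrected: Volume
    mask: BinaryMask
    n_perm: int
    contrast: tuple[str, str]
    E: float = TFCE_E
    H: float = TFCE_H
    dh: float = TFCE_DH


def tfce_enhance(
    stat: np.ndarray,
    mask: np.ndarray,
    E: float = TFCE_E,
    H: float = TFCE_H,
    dh: float = TFCE_DH,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a (positive) statistic map.

    TFCE(v) = sum over thresholds h = dh, 2dh, ... <= max(stat) of
    e(h, v)^E * h^H * dh, where e(h, v) is the voxel count of the
    26-connected suprathreshold component containing v (within the
    mask).  Non-positive statistic values enhance to zero.
    """
    stat = np.where(mask, stat, 0.0)
    out = np.zeros_like(stat, dtype=np.float64)
    smax = float(stat.max(initial=0.0))
    if smax <= 0:
        return out
    structure = np.ones((3, 3, 3), dtype=int)
    n_steps = int(np.floor(smax / dh + 1e-9))
    for i in range(1, n_steps + 1):
        h = i * dh
        supra = stat >= h
        if not supra.any():
            break
        labels, n_lab = ndimage.label(supra, structure=structure)
        sizes = np.bincount(labels.ravel())
        out[supra] += sizes[labels[supra]] ** E * h**H * dh
    return out


def _t_stat_matrix(data: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column of (n_subjects, n_voxels)."""
    a, b = data[is_a], data[~is_a]
    na, nb = len(a), len(b)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (ma - mb) / se, 0.0)
    return t


def voxelwise_permutation_tfce(
    volumes: list[Volume],
    labels: list[str],
    mask: BinaryMask,
    contrast: tuple[str, str] | None = None,
    n_perm: int = DEFAULT_N_PERM,
    E: float = TFCE_E,
    H: float = TFCE_H,
    dh: float = TFCE_DH,
    seed: int = 0,
) -> VoxelwiseResult:
    """Permutation test of a two-group voxelwise difference with TFCE FWE.

    The raw statistic is the pooled two-sample t for contrast[0] minus
    contrast[1] at every mask voxel; its TFCE enhancement is compared
    against the null distribution of the maximum TFCE statistic over
    ``n_perm`` random label permutations:
    p_corr(v) = (1 + #{perm max-TFCE >= TFCE(v)}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives meaningless FWE resolution")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    if contrast is None:
        contrast = (uniq[0], uniq[1])
    if set(contrast) != set(uniq):
        raise ValueError(f"contrast {contrast} does not match labels {uniq}")
    assert_same_grid([*volumes, mask])
    mask_bool = mask.data.astype(bool)
    if not mask_bool.any():
        raise ValueError("empty mask")
    # restrict work to the mask bounding box
    bbox = tuple(
        slice(int(idx.min()), int(idx.max()) + 1) for idx in np.nonzero(mask_bool)
    )
    sub_mask = mask_bool[bbox]
    flat = sub_mask.ravel()
    data = np.stack([v.data[bbox].reshape(-1)[flat] for v in volumes])
    is_a = np.asarray([lab == contrast[0] for lab in labels])

    def tfce_of(is_a_perm: np.ndarray) -> np.ndarray:
        t = _t_stat_matrix(data, is_a_perm)
        grid = np.zeros(sub_mask.shape)
        grid.reshape(-1)[flat] = t
        return tfce_enhance(grid, sub_mask, E, H, dh)

    t_obs = _t_stat_matrix(data, is_a)
    stat_grid = np.zeros(sub_mask.shape)
    stat_grid.reshape(-1)[flat] = t_obs
    tfce_obs = tfce_enhance(stat_grid, sub_mask, E, H, dh)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        null_max[p] = tfce_of(rng.permutation(is_a)).max()

    obs_vals = tfce_obs[sub_mask]
    exceed = (null_max[None, :] >= obs_vals[:, None]).sum(axis=1)
    p_vals = (1.0 + exceed) / (n_perm + 1.0)

    full = lambda sub: _embed(sub, mask_bool.shape, bbox)
    p_grid = np.ones(sub_mask.shape)
    p_grid[sub_mask] = p_vals
    return VoxelwiseResult(
        stat=Volume(full(stat_grid), mask.affine),
        tfce=Volume(full(tfce_obs), mask.affine),
        p_corrected=Volume(_embed(p_grid, mask_bool.shape, bbox, fill=1.0), mask.affine),
        mask=mask,
        n_perm=n_perm,
        contrast=contrast,
        E=E,
        H=H,
        dh=dh,
    )


def _embed(sub: np.ndarray, shape: tuple, bbox: tuple, fill: float = 0.0) -> np.ndarray:
    out = np.full(shape, fill, dtype=np.float64)
    out[bbox] = sub
    return out


def mask_statmap_by_portion(
    result: VoxelwiseResult, atlas: ProbabilisticAtlas, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Count significant voxels (corrected p < alpha) inside each portion."""
    assert_same_grid(
        [result.p_corrected, next(iter(atlas.portions.values()))], ["p_map", "atlas"]
    )
    sig = result.p_corrected.data < alpha
    rows = []
    for pid in PORTION_IDS:
        support = atlas.support(pid)
        n_support = int(support.sum())
        n_sig = int((support & sig).sum())
        rows.append(
            {"portion": pid, "n_voxels": n_support, "n_significant": n_sig,
             "fraction_significant": n_sig / n_support if n_support else 0.0}
        )
    return pd.DataFrame(rows)
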