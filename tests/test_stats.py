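import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ccfa import (
    BinaryMask,
    PORTION_IDS,
    RegionalFATable,
    Volume,
    anova_f_from_summary,
    anova_pairwise,
    logistic_detect,
    mask_statmap_by_portion,
    tfce_enhance,
    voxelwise_permutation_tfce,
)
from ccfa.phantom import GROUP_FA_PARAMS, GROUP_SIZES
from ccfa.stats import ClassificationResult, VoxelwiseResult


def exact_moment_sample(rng, n, mean, sd):
    """A sample with exactly the requested mean and sample SD."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


def make_table(values_by_group, portion_value=None):
    """Build a RegionalFATable with identical values in all portions."""
    rows = []
    for g, vals in values_by_group.items():
        for i, v in enumerate(vals):
            rows.append(
                {"subject_id": f"{g}_{i}", "group": g, **{p: v for p in PORTION_IDS}}
            )
    return RegionalFATable(pd.DataFrame(rows), fa_min=0.0)


class TestAnova:
    def test_identical_constants_give_f_zero_p_one(self):
        table = make_table({"AD": [0.5] * 4, "aMCI": [0.5] * 4, "HC": [0.5] * 4})
        res = anova_pairwise(table)
        assert (res.table["F"] == 0).all()
        assert (res.table["p_corrected"] == 1.0).all()
        assert not res.table["significant"].any()

    def test_summary_statistic_oracle(self, rng):
        """F on raw data equals the closed-form F from (n, mean, SD)
        summaries, using the published CC1 group moments."""
        ns = [GROUP_SIZES[g] for g in ("AD", "aMCI", "HC")]
        moments = [GROUP_FA_PARAMS[g]["CC1"] for g in ("AD", "aMCI", "HC")]
        samples = {
            g: exact_moment_sample(rng, n, m, s)
            for g, n, (m, s) in zip(("AD", "aMCI", "HC"), ns, moments)
        }
        table = make_table(samples)
        res = anova_pairwise(table)
        f_raw = res.table.loc[res.table["portion"] == "CC1", "F"].iloc[0]
        f_summary, _ = anova_f_from_summary(ns, [m for m, _ in moments], [s for _, s in moments])
        assert f_raw == pytest.approx(f_summary, abs=1e-8)
        # independent library oracle on the same data
        f_scipy, _ = sps.f_oneway(*samples.values())
        assert f_raw == pytest.approx(f_scipy, abs=1e-8)

    def test_pairwise_uses_pooled_error_term(self, rng):
        """The AD-HC t statistic is reconstructed from the pooled
        within-group mean square with N - k degrees of freedom."""
        samples = {
            "AD": exact_moment_sample(rng, 10, 0.42, 0.03),
            "aMCI": exact_moment_sample(rng, 8, 0.44, 0.03),
            "HC": exact_moment_sample(rng, 9, 0.47, 0.02),
        }
        table = make_table(samples)
        res = anova_pairwise(table)
        row = res.table[
            (res.table["portion"] == "CC1")
            & (res.table["group_a"] == "AD")
            & (res.table["group_b"] == "HC")
        ].iloc[0]
        ssw = sum(np.sum((v - v.mean()) ** 2) for v in samples.values())
        df_w = 27 - 3
        msw = ssw / df_w
        t = (samples["AD"].mean() - samples["HC"].mean()) / np.sqrt(msw * (1 / 10 + 1 / 9))
        p = 2 * sps.t.sf(abs(t), df_w)
        assert row["p_raw"] == pytest.approx(p, abs=1e-12)
        assert row["p_corrected"] == pytest.approx(min(1.0, 3 * p), abs=1e-12)

    def test_bonferroni_bound(self, small_table):
        res = anova_pairwise(small_table)
        assert (res.table["p_corrected"] >= res.table["p_raw"] - 1e-15).all()
        assert (res.table["p_corrected"] <= 1.0).all()
        np.testing.assert_allclose(
            res.table["p_corrected"],
            np.minimum(1.0, 3 * res.table["p_raw"]),
        )

    def test_doubling_alpha_keeps_significance(self, small_table):
        lo = anova_pairwise(small_table, alpha=0.05)
        hi = anova_pairwise(small_table, alpha=0.10)
        assert np.all(hi.table["significant"] | ~lo.table["significant"])

    def test_small_group_rejected(self):
        table = make_table({"AD": [0.4], "HC": [0.5, 0.52]})
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_pairwise(table)


class TestLogisticDetect:
    def test_perfectly_separable_groups(self, rng):
        ad = {p: list(rng.uniform(0.30, 0.38, 10)) for p in PORTION_IDS}
        hc = {p: list(rng.uniform(0.55, 0.65, 10)) for p in PORTION_IDS}
        rows = []
        for i in range(10):
            rows.append({"subject_id": f"AD_{i}", "group": "AD", **{p: ad[p][i] for p in PORTION_IDS}})
            rows.append({"subject_id": f"HC_{i}", "group": "HC", **{p: hc[p][i] for p in PORTION_IDS}})
        table = RegionalFATable(pd.DataFrame(rows), fa_min=0.0)
        with pytest.warns(UserWarning, match="separation"):
            res = logistic_detect(table, ("AD", "HC"), seed=1)
        assert res.overall == 1.0
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0

    def test_null_features_heldout_accuracy_near_chance(self):
        """With labels independent of all features and balanced groups, the
        held-out 20% accuracy averages the majority-class rate (0.5); the
        resubstitution rate is optimistically biased at finite n and is
        checked only for being above chance."""
        n_sims = 60
        unsel, overall = [], []
        for s in range(n_sims):
            rng = np.random.default_rng(1000 + s)
            rows = []
            for g in ("AD", "HC"):
                for i in range(30):
                    rows.append(
                        {"subject_id": f"{g}_{i}", "group": g,
                         **{p: rng.normal(0.5, 0.05) for p in PORTION_IDS}}
                    )
            table = RegionalFATable(pd.DataFrame(rows), fa_min=0.0)
            res = logistic_detect(table, ("AD", "HC"), seed=s)
            unsel.append(res.cv_unselected)
            overall.append(res.overall)
        se = np.std(unsel, ddof=1) / np.sqrt(n_sims)
        assert abs(np.mean(unsel) - 0.5) < 3 * se + 1e-9
        assert np.mean(overall) > 0.5

    def test_confusion_matrix_arithmetic(self):
        """Metrics are exactly the ratios of a constructed confusion matrix
        (TP=35, FN=2, TN=16, FP=4)."""
        res = ClassificationResult(
            contrast=("AD", "HC"),
            overall=51 / 57,
            sensitivity=35 / 37,
            specificity=16 / 20,
            confusion={"tp": 35, "fn": 2, "tn": 16, "fp": 4},
            cv_selected=0.9,
            cv_unselected=0.9,
            seed=0,
        )
        assert res.overall == pytest.approx(0.8947, abs=5e-5)
        assert res.sensitivity == pytest.approx(0.9459, abs=5e-5)
        assert res.specificity == pytest.approx(0.80, abs=1e-12)

    def test_inconsistent_confusion_matrix_rejected(self):
        with pytest.raises(AssertionError):
            ClassificationResult(
                contrast=("AD", "HC"), overall=0.99, sensitivity=35 / 37,
                specificity=0.8, confusion={"tp": 35, "fn": 2, "tn": 16, "fp": 4},
                cv_selected=0.9, cv_unselected=0.9, seed=0,
            )

    def test_fitted_metrics_recomputable_from_confusion(self, small_table):
        res = logistic_detect(small_table, ("AD", "HC"), seed=3)
        c = res.confusion
        n = sum(c.values())
        assert res.overall == pytest.approx((c["tp"] + c["tn"]) / n)

    def test_too_few_subjects_rejected(self):
        table = make_table({"AD": [0.4] * 3, "HC": [0.5] * 8})
        with pytest.raises(ValueError, match=">= 5"):
            logistic_detect(table, ("AD", "HC"), seed=0)


class TestTFCE:
    def test_zero_statistic_enhances_to_zero(self):
        mask = np.ones((6, 6, 6), dtype=bool)
        out = tfce_enhance(np.zeros((6, 6, 6)), mask)
        assert np.all(out == 0)

    def test_single_voxel_brute_force_sum(self):
        """An isolated suprathreshold voxel with statistic 2.0 enhances to
        sum over h in {0.1, ..., 2.0} of 1^0.5 * h^2 * 0.1."""
        stat = np.zeros((5, 5, 5))
        stat[2, 2, 2] = 2.0
        mask = np.ones((5, 5, 5), dtype=bool)
        out = tfce_enhance(stat, mask, E=0.5, H=2.0, dh=0.1)
        expected = sum(1**0.5 * (0.1 * k) ** 2 * 0.1 for k in range(1, 21))
        assert out[2, 2, 2] == pytest.approx(expected, abs=1e-12)
        assert np.count_nonzero(out) == 1

    def test_cluster_extent_enters_enhancement(self):
        """Two 26-connected voxels share a component of size 2 at every
        threshold, so enhancement uses e = 2."""
        stat = np.zeros((5, 5, 5))
        stat[2, 2, 2] = stat[2, 2, 3] = 1.0
        out = tfce_enhance(stat, np.ones((5, 5, 5), dtype=bool), E=0.5, H=2.0, dh=0.1)
        expected = sum(2**0.5 * (0.1 * k) ** 2 * 0.1 for k in range(1, 11))
        assert out[2, 2, 2] == pytest.approx(expected, abs=1e-12)

    def test_scaling_monotonicity(self, rng):
        stat = rng.normal(0, 1, (8, 8, 8))
        mask = np.ones((8, 8, 8), dtype=bool)
        a = tfce_enhance(stat, mask)
        b = tfce_enhance(1.5 * stat, mask)
        assert np.all(b >= a - 1e-12)


class TestVoxelwisePermutation:
    @staticmethod
    def _null_volumes(rng, n=16, shape=(8, 8, 8)):
        return [Volume(np.clip(rng.normal(0.5, 0.05, shape), 0, 1)) for _ in range(n)]

    def test_low_n_perm_rejected(self, rng):
        vols = self._null_volumes(rng, 6)
        labels = ["AD"] * 3 + ["HC"] * 3
        with pytest.raises(ValueError, match="n_perm"):
            voxelwise_permutation_tfce(vols, labels, BinaryMask(np.ones((8, 8, 8))), n_perm=50)

    def test_p_values_bounded_below_by_permutation_resolution(self, rng):
        vols = self._null_volumes(rng)
        labels = ["AD"] * 8 + ["HC"] * 8
        res = voxelwise_permutation_tfce(
            vols, labels, BinaryMask(np.ones((8, 8, 8))), n_perm=120, seed=5
        )
        assert res.p_corrected.data.min() >= 1 / 121 - 1e-12
        assert res.p_corrected.data.max() <= 1.0

    def test_fwe_validity_under_null(self):
        """With identical group distributions the family-wise rate of any
        corrected p < 0.05 stays near the nominal 5% over replicates."""
        n_reps = 12
        false_alarms = 0
        for rep in range(n_reps):
            rng = np.random.default_rng(9000 + rep)
            vols = self._null_volumes(rng)
            labels = ["AD"] * 8 + ["HC"] * 8
            res = voxelwise_permutation_tfce(
                vols, labels, BinaryMask(np.ones((8, 8, 8))), n_perm=150, seed=rep
            )
            if (res.p_corrected.data < 0.05).any():
                false_alarms += 1
        # P(X >= 4 | Binomial(12, 0.05)) < 0.003
        assert false_alarms <= 3

    def test_strong_effect_detected(self, rng):
        shape = (8, 8, 8)
        effect = np.zeros(shape)
        effect[2:6, 2:6, 2:6] = 0.15
        vols = [Volume(np.clip(rng.normal(0.5, 0.02, shape) + effect, 0, 1)) for _ in range(8)]
        vols += [Volume(np.clip(rng.normal(0.5, 0.02, shape), 0, 1)) for _ in range(8)]
        labels = ["HC"] * 8 + ["AD"] * 8
        res = voxelwise_permutation_tfce(
            vols, labels, BinaryMask(np.ones(shape)), contrast=("HC", "AD"),
            n_perm=200, seed=3,
        )
        assert (res.p_corrected.data[3, 3, 3]) < 0.05
        assert res.p_corrected.data[0, 0, 0] > 0.05

    def test_determinism(self, rng):
        vols = self._null_volumes(rng)
        labels = ["AD"] * 8 + ["HC"] * 8
        mask = BinaryMask(np.ones((8, 8, 8)))
        a = voxelwise_permutation_tfce(vols, labels, mask, n_perm=120, seed=11)
        b = voxelwise_permutation_tfce(vols, labels, mask, n_perm=120, seed=11)
        np.testing.assert_array_equal(a.p_corrected.data, b.p_corrected.data)


class TestMaskStatmapByPortion:
    @staticmethod
    def _result_with_p(atlas, p_data):
        grid = atlas.grid_shape
        return VoxelwiseResult(
            stat=Volume(np.zeros(grid), atlas.affine),
            tfce=Volume(np.zeros(grid), atlas.affine),
            p_corrected=Volume(p_data, atlas.affine),
            mask=atlas.union_mask(),
            n_perm=1000,
            contrast=("HC", "AD"),
        )

    def test_all_p_one_gives_zero_counts(self, small_atlas):
        res = self._result_with_p(small_atlas, np.ones(small_atlas.grid_shape))
        counts = mask_statmap_by_portion(res, small_atlas, 0.05)
        assert (counts["n_significant"] == 0).all()

    def test_single_portion_fully_significant(self, small_atlas):
        p = np.ones(small_atlas.grid_shape)
        p[small_atlas.support("CC3")] = 0.01
        res = self._result_with_p(small_atlas, p)
        counts = mask_statmap_by_portion(res, small_atlas, 0.05).set_index("portion")
        assert counts.loc["CC3", "fraction_significant"] == 1.0
        others = counts.drop("CC3")
        assert (others["fraction_significant"] == 0).all()

    def test_disjoint_portions_sum_equals_union_count(self, small_atlas, rng):
        p = np.where(rng.random(small_atlas.grid_shape) < 0.3, 0.01, 1.0)
        res = self._result_with_p(small_atlas, p)
        counts = mask_statmap_by_portion(res, small_atlas, 0.05)
        union = small_atlas.union_mask().data.astype(bool)
        union_count = int(((p < 0.05) & union).sum())
        assert counts["n_significant"].sum() == union_count
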