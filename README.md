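# ccfa — corpus callosum FA analysis with a probabilistic tract atlas

`ccfa` implements a regional fractional-anisotropy (FA) measurement for
the corpus callosum (CC) aimed at studies of white-matter damage in
Alzheimer's disease (AD) and amnestic mild cognitive impairment (aMCI):
a probabilistic atlas of the CC divided into **eight portions** (CC1
orbital frontal, CC2 anterior frontal, CC3 superior frontal, CC4
superior parietal, CC5 posterior parietal, CC6L/CC6R left/right
temporal, CC7 occipital) is built from per-subject tract density maps,
and per-subject regional FA is extracted as a probability-weighted
average over each portion. A simplified skeleton-projection (TBSS-style)
arm, the group statistics used with both arms, and a synthetic phantom
cohort generator for validating the whole chain are included.

It is intended for methods researchers who want a transparent, testable
implementation of the atlas-based measurement and its comparison
baseline, not as a replacement for a full neuroimaging preprocessing
stack: FA maps and density maps are assumed already co-registered to one
grid (registration, tensor fitting and tractography are out of scope).

## The measurement

**Atlas construction.** For each of `n` atlas subjects, the binary
(binarised) density map of portion `k` is averaged voxelwise, giving the
membership probability `p_k(v) ∈ {0, 1/n, …, 1}`. Probabilities below a
retention threshold `τ` (default 0.90) are set to zero; values `≥ τ`
keep their original value.

**Probability-weighted regional FA.** For subject `s` and portion `k`,

```
FA_k(s) = Σ_v p_k(v) · FA_s(v) / Σ_v p_k(v),   over v with p_k(v) > 0 and FA_s(v) ≥ 0.2
```

Voxels with FA below 0.2 are rejected before averaging, protecting the
estimate from CSF/grey-matter partial-volume contamination at tract
borders.

**Skeleton arm.** A mean-FA template is thresholded at 0.2 and reduced
to its ridge; each subject's FA is projected onto the skeleton by taking
the maximum FA within ±4 voxels along the local tract-perpendicular, and
regional means are taken over skeleton voxels inside each atlas portion.

**Statistics.** Per portion: one-way ANOVA across groups with pairwise
post-hoc t tests on the pooled error term, Bonferroni-corrected within
portion (`p_corr = min(1, 3p)` for the three contrasts AD–HC, aMCI–HC,
aMCI–AD). Group detection: logistic regression on all 8 portion means
with apparent accuracy, sensitivity/specificity, and a stratified 80/20
cross-validation. Voxelwise: two-sample t maps enhanced with
threshold-free cluster enhancement, `TFCE(v) = Σ_h e(h,v)^E · h^H · dh`
(E = 0.5, H = 2, dh = 0.1, 26-connectivity), with family-wise-error
corrected p-values from the permutation distribution of the maximum TFCE
statistic (default 5000 permutations).

## Worked example

Generate a phantom study cohort (group sizes 37 AD / 19 aMCI / 20 HC,
plus 25 atlas subjects), build the atlas, extract regional FA and run
the group comparison:

```python
import ccfa

cfg = ccfa.PhantomConfig()                       # published group FA parameters
maps = ccfa.generate_density_maps(cfg, cfg.n_atlas_subjects, seed=2)
atlas = ccfa.build_atlas(maps, tau=0.90)

vols, manifest = ccfa.generate_fa_cohort(cfg, {"AD": 37, "aMCI": 19, "HC": 20}, seed=1)
volumes = {r.subject_id: v for r, v in zip(manifest, vols)}
table = ccfa.extract_table(manifest, atlas, fa_min=0.2, volumes=volumes)

summary = table.group_summary()
print(summary[summary.portion == "CC1"].to_string(index=False))

res = ccfa.anova_pairwise(table, alpha=0.05)
cc1 = res.table[res.table.portion == "CC1"]
print(cc1[["group_a", "group_b", "F", "p_corrected", "significant"]].to_string(index=False))
```

prints

```
portion group  n  mean_fa    sd_fa
    CC1    AD 37 0.420017 0.030083
    CC1    HC 20 0.462067 0.017086
    CC1  aMCI 19 0.444882 0.030577
group_a group_b        F  p_corrected  significant
     AD      HC 16.21456     0.000001         True
   aMCI      HC 16.21456     0.163199        False
   aMCI      AD 16.21456     0.005904         True
```

The extracted group means match the parameters that generated the cohort
(AD 0.42, aMCI 0.44, HC 0.47 for CC1), and the orbital-frontal portion
separates AD from both HC and aMCI but not aMCI from HC — the frontal
sparing pattern expected at the prodromal stage.

The same flow is available from the shell:

```sh
ccfa phantom generate --out cohort --seed 1
ccfa atlas build --manifest cohort/density/atlas_manifest.csv \
                 --density-dir cohort/density --tau 0.90 --out atlas_dir
ccfa extract atlas-fa --manifest cohort/manifest.csv --atlas atlas_dir \
                      --fa-min 0.2 --out regional_fa.csv
ccfa stats anova --table regional_fa.csv --alpha 0.05 --out anova.csv
ccfa run --config study.yaml       # the whole study in one step
```

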