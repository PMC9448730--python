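# stepconn

Stepwise functional connectivity (SFC) analysis of resting-state fMRI, built
to study how cerebro-cerebellar networks differ between Parkinson's disease
motor subtypes (tremor-dominant, TD, vs postural-instability-gait-disorder,
PIGD) and to flag TD patients at risk of converting to PIGD.

It is aimed at researchers who want the full voxelwise SFC pipeline as a
tested, reusable library: nuisance cleaning and motion QC, voxel-by-voxel
network construction, the recursive stepwise connectivity metric, TFCE
permutation inference with covariate adjustment, and ROC-based conversion
prediction — plus a synthetic cohort generator with planted ground truth so
every stage can be validated end to end without access to clinical data.

## The metric

For a subject's cleaned voxel time series, the association matrix `A` holds
the Fisher-z transform of every positive, FDR-significant (Benjamini–Hochberg,
q = 0.05) voxel–voxel Pearson correlation, and zero elsewhere. Stepwise
connectivity counts weighted walks of exact length *l* between a voxel and a
seed region:

    A_1(i, j) = A(i, j)                                      (i ≠ j)
    A_l(i, j) = Σ_k  norm(A_{l-1})(i, k) · norm(A)(k, j)     (i ≠ j, l ≥ 2)

where `norm` rescales the off-diagonal entries to [0, 1] (min–max), applied
at every step so maps are comparable across link-step distances. The seed map
at step *l* is `s_l(j) = Σ_{i∈seed} A_l(i, j)`: "direct" connectivity is
l = 1, "indirect" is l = 2–4 (consecutive maps stabilize above four steps,
approaching the dominant-eigenvector direction of the normalized matrix).
Group contrasts are voxelwise GLMs (group + age + sex), enhanced with
threshold-free cluster enhancement (H = 2, E = 0.5, 26-connectivity) and
family-wise-error corrected with the permutation distribution of the
image-wide maximum TFCE statistic (Freedman–Lane residual permutation).

## Worked example

Simulate a cohort with a +20% connectivity modulation planted on the
community two link-steps from the seed in the PIGD group, then recover it:

```python
import pandas as pd
import stepconn as sc

bp = sc.make_blueprint(seed=0)                      # 10x10x10 grid, TR 3 s
print(bp.graph_distances())
# {'seed': 0, 'c1': 1, 'c2': 2, 'c3': 3}

specs, series, truth = sc.simulate_cohort(
    bp, {"PD_PIGD": 26, "PD_TD": 30},
    planted_effect={"community": "c2", "multiplier": 1.2, "group": "PD_PIGD"},
    seed=3)

maps = sc.cohort_sfc_maps(series, bp.communities["seed"], L_max=4)

table = pd.DataFrame([{"group": s.group, "age": s.age, "sex": s.sex}
                      for s in specs])
model = sc.StepwiseGroupModel.from_table(maps[1], table,
                                         ("PD_PIGD", "PD_TD"), bp.mask)
result = model.fit(n_perm=500, seed=1)
print(result.summary())
```

This prints:

```
Stepwise connectivity group comparison
  n subjects: 56, voxels: 552
  increase: 195 significant voxels (FWE p < 0.05, 500 permutations, df=52)
  decrease: 0 significant voxels (FWE p < 0.05, 500 permutations, df=52)
direction  cluster  size   peak_t  peak_fwe_p peak_voxel
 increase        1   195 7.663963    0.001996  (7, 8, 7)
```

One cluster of 195 voxels shows FWE-significant *increased* direct stepwise
connectivity in the PIGD group (peak t = 7.66 at voxel (7, 8, 7), FWE
p = 0.002 from 500 permutations), and nothing survives in the decrease
direction. The cluster coincides with the community whose coupling was
modulated — the Dice overlap with the planted ground-truth mask is 1.00 for
this cohort. The per-subject stability profile
(`sc.stability_profile`) for the same data reads
`{1: 0.974, 2: 0.998, 3: 1.0, 4: 1.0, 5: 1.0}`: consecutive step maps are
already correlated above 0.95 from step 4 on, which is why analyses use
steps 1–4.

Conversion prediction (`sc.extract_features`, `sc.ConversionModel`) scores
clinical features (Hoehn & Yahr, UPDRS total, FOG-Q) and mean SFC inside the
significant clusters at steps 1 and 4, separately and combined, reporting
ROC curves, Mann–Whitney AUCs and stratified-bootstrap 95% CIs.

A `stepconn` command-line tool wraps each stage
(`simulate`, `preprocess`, `network`, `sfc`, `seedmap`, `groupstats`, `roc`);
run `stepconn --help` for usage.

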