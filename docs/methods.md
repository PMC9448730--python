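# Methods

This note records the models, parameter choices and numerical conventions
behind `stepconn`, and what the synthetic validation does and does not show
about real data.

## Stepwise connectivity

The association matrix `A` is built per subject from the cleaned voxel × time
matrix: Pearson correlation between every in-mask voxel pair, Fisher z
transform, one-sided p-values for positive association from
`t = r·sqrt((n−2)/(1−r²))` on `n − 2` degrees of freedom, and
Benjamini–Hochberg FDR at q = 0.05 over the upper-triangle edge family of
that subject's matrix. Retained edges keep their Fisher-z value; negative or
non-significant edges are zero. Conventions worth stating:

- **One-sided test by default.** Only positive edges can enter the network,
  so the default test is of positive association (a two-sided option exists).
- **Degrees of freedom.** `n − 2` with `n` the number of time points,
  ignoring the autocorrelation that band-pass filtering induces. This is a
  known simplification: on band-limited data the null variance of z exceeds
  `1/(n−3)`, so edge p-values are anticonservative there. The FDR
  calibration property is therefore asserted on serially uncorrelated
  (white-noise) null data, where it holds.
- **Duplicated voxels** (|r| = 1) carry a capped z sentinel and are excluded
  from the edge family rather than propagating infinities.

The step-l matrices follow the recursion
`A_l = norm(A_{l−1}) · norm(A)` (off-diagonal only), where `norm` min–max
scales the off-diagonal entries to [0, 1]. Choices:

- min/max are taken over off-diagonal entries only; the diagonal is set to 0
  in every normalized matrix (the recursion defines only i ≠ j entries).
- A degenerate matrix (max = min) normalizes to all zeros, which terminates
  propagation instead of dividing by zero.
- Walks may revisit voxels and the seed; no simple-path pruning.
- The second factor is always the normalized original `A`, not a
  re-normalized `A_1`.
- Positive rescaling of `A` leaves every normalized `A_l` unchanged — the
  min–max map removes scale, which is what makes maps comparable across
  subjects and steps.
- **Asymmetry at l ≥ 3.** `A_2 = norm(A)²` is exactly symmetric, but for
  l ≥ 3 the recursion multiplies two *different* symmetric matrices, which
  need not commute (both the zeroed diagonal and the additive min–max offset
  break commutativity), so `A_l` is only approximately symmetric from three
  steps on. We keep the recursion literal — the vectorized implementation is
  tested to 1e-10 against a triple-loop transcription — and read seed maps as
  `s_l(j) = Σ_{i∈seed} A_l(i, j)` with the seed indexing rows.
- Seed aggregation is a sum over seed voxels by default (the "any seed
  voxel" path count); a mean option exists.

The stability profile correlates consecutive seed maps over non-seed voxels.
Because each step is a normalized matrix power, the maps converge to the
dominant-eigenvector direction of the normalized association matrix
(power iteration), which is why consecutive-map correlations approach 1 and
analyses restrict to steps 1–4.

## Preprocessing

Operating order: drop the first 4 volumes, one-shot OLS nuisance regression,
then band-pass; network construction always runs on filtered residuals.

- **Framewise displacement**: Power formulation,
  `FD_t = Σ|Δtrans| + r·Σ|Δrot|` with head radius r = 50 mm.
- **Scrubbing**: volumes with FD > 0.5 mm are flagged together with 1 back
  and 2 forward neighbours; each flagged volume becomes a 0/1 spike
  regressor. QC fails when more than 90 volumes are flagged (inclusive
  boundary: 90 passes, 91 fails). The companion duration phrasing of this
  rule ("at least 5 min 30 s") is inconsistent with the count rule at
  TR = 3 s and is not enforced.
- **Nuisance set**: intercept, Friston-24 motion expansion
  ([p, p_{t−1}, p², p_{t−1}²], first-volume lag zero-padded), spike
  regressors, linear and quadratic trends, and global/white-matter/CSF mean
  signals when supplied (the driver defaults to the in-mask global mean; no
  tissue segmentation is attempted on synthetic grids). Exactly duplicated
  columns are dropped; remaining rank deficiency is an error naming the
  collinear columns, except in the pipeline driver, which drops them with a
  warning (degenerate motion traces make quadratic terms exactly collinear).
- **Band-pass 0.01–0.08 Hz**: an ideal FFT-domain filter with hard cutoffs
  after linear detrending. The transfer function is exactly reproducible
  (bin-wise 0/1), at the price of ringing that a Butterworth design would
  trade differently; the passband/stopband contract (0.05 Hz ratio > 0.8,
  0.15 Hz ratio < 0.1 at TR = 3 s) is what downstream stages rely on.
- Spatial smoothing is available as an optional Gaussian blur and is off by
  default on synthetic grids.

## Seed definition from task data

The motor seed stands in for a task-localized cerebellar region: a boxcar
for ~19 s alternating activation blocks convolved with a canonical
double-gamma HRF (gamma shapes 6 and 16, unit scale, undershoot ratio 1/6),
plus intercept and linear drift; per-voxel OLS t-maps; a group one-sample
t-test across subjects; threshold at voxelwise p < 0.001 (one-sided),
removal of clusters below a minimum extent (26-connectivity) in place of an
anatomically-informed small-volume correction; and majority-vote
downsampling to the 5 mm analysis grid.

## Group inference

Per voxel, the step-l map value is regressed on group, age and sex; the
group-contrast t-map is enhanced with TFCE
(`TFCE(v) = Σ_h e(h,v)^E · h^H · dh`, H = 2, E = 0.5, dh = max/100,
26-connectivity — the standard volumetric parameterization) and compared to
the permutation distribution of the image-wide maximum TFCE under the
Freedman–Lane scheme (maps residualized on the covariate-only model, residual
rows permuted, full model re-fitted). `FWE p(v) = (1 + #{max_null ≥ TFCE(v)})
/ (n_perm + 1)`; the default is 5000 permutations, and each contrast
direction and each link step is its own family.

The TFCE implementation activates voxels in descending height order and
merges clusters with a union-find structure, accumulating per-member
increments lazily; it is exactly equivalent (machine precision) to naive
per-threshold connected-component labelling on the same discrete threshold
ladder, and the isolated-voxel limit `t^(H+1)/(H+1)` is recovered as
dh → 0. Suprathreshold is `value ≥ h` on the ladder `h = dh, 2dh, …, max`.

## Conversion prediction

Features are the three clinical scores (Hoehn & Yahr, UPDRS total, FOG-Q)
and the mean step-map value inside each significant cluster of the
converter-vs-non-converter contrast at steps 1 (direct) and 4 (indirect).
Clusters from the decrease direction contribute sign-flipped features so
that higher always points toward the converter-like pattern. Single-feature
sets are scored raw (AUC is rank-invariant); multi-feature sets by an
L2-regularized logistic score on z-scored features, fitted in sample to
mirror the small-cohort design this models (n = 10 vs 18); a leave-one-out
mode (`cv="loo"`) is provided and is the recommended honest evaluation. AUC
is the Mann–Whitney statistic with ties counted 1/2 (identical to the
trapezoid area); 95% CIs come from a stratified bootstrap (2000 replicates,
seeded). With perfect separation the regularized score stays finite and the
result is flagged.

## Synthetic cohorts

Each subject is `x_v(t) = w_in · u_k(t) + noise_sd · ε_v(t)` for voxel v in
community k, with unit-variance community latents whose correlation matrix
follows the community graph: adjacent communities correlate at the edge
weight, non-adjacent ones at the product along the shortest path (exact and
positive definite on the default chain; eigenvalue-clipped otherwise). The
expected voxel correlation is `w_in²/(w_in²+noise_sd²)` within a community,
scaled by the latent correlation between communities. Defaults, chosen once:

- grid 10×10×10, ellipsoidal mask (~550 in-mask voxels) so the full
  voxel×voxel matrix stays desk-scale;
- 4 communities in a chain (seed at distance 0, c3 at distance 3), compact
  slabs along the first axis;
- 30% of in-mask voxels are *background* noise voxels belonging to no
  community. They play the role that sub-threshold tissue plays in real
  data: they guarantee genuinely null edges in every association matrix,
  which anchors the off-diagonal minimum at zero. Without them a strongly
  coupled network can reach edge density 1, the minimum leaves zero, and the
  min–max normalization regime changes discontinuously (a planted increase
  can then surface as spurious decreases elsewhere);
- `w_in = 0.9`, `w_between = 0.75`, `noise_sd = 0.5`, TR = 3 s, 200 volumes,
  latents and voxel noise band-limited to 0.01–0.08 Hz so the pipeline's own
  band-pass leaves planted correlations intact. Calibration properties that
  invoke the white-noise sampling theory of correlations (Fisher-z null,
  FDR) use `band_limit=False` configurations, where that theory applies.
- motion traces are smooth random walks (0.02 mm / 2e-4 rad steps); spikes
  are injected only on request and produce an FD excursion equal to the
  requested amplitude.

**Planted effects.** A planted multiplier m on community P rescales the
expected *Fisher-z strength* of every community-graph edge touching P by m —
Fisher z being the unit in which the pipeline measures connectivity — by
solving for the latent edge correlation that achieves the target. Voxel
amplitude and within-community coherence are untouched, so the modulation is
purely a coupling change; an amplitude modulation would move the min–max
normalizer of the whole matrix and contaminate every other edge. The
ground-truth mask contains every community whose latent coupling *to the
seed* changes under the modulation (the modulated community and any
community whose path to the seed crosses a modulated edge), which is exactly
what seed-anchored maps can detect. With the defaults above, a +20%
modulation realizes a voxel-level group effect of d ≈ 1 at the target
community for n = 30 vs 26 — the regime the recovery checks assume.
Converter cohorts (10 cPD-TD vs 18 ncPD-TD) use a stronger default
modulation (1.35) so that the n = 28 contrast yields significant clusters at
both the direct and indirect steps, mirroring the data regime the ROC
analysis models; clinical scores are drawn from the cohort baselines
(HY 1.45 ± 0.76, UPDRS 30 ± 12, FOG-Q 1.50 ± 1.43) with converters shifted
by the requested Cohen-d.

**What the generator does not emulate.** Anatomy, registration, scanner
physics and slice timing are out of scope. More importantly, the latent
structure is extremely low-rank (one latent per community), with two
consequences. First, per-voxel between-subject variability is floored at the
sampling error of a single correlation, so planted effects translate into
group effect sizes less favourably than the nominal multiplier suggests.
Second, the global mean signal nearly coincides with the latent mixture, so
global-signal regression removes most of the planted coupling change
(measured: recovery Dice drops from ~1 to 0 when the cleaning driver's GSR
runs on generator output). Real data, with thousands of partially correlated
sources, are far less sensitive to this; the recovery experiments therefore
run on the generator's output directly, which the generator defines as
already-cleaned series, while the cleaning stage is validated by its own
contracts. Passing recovery tests show the metric and the inference
machinery work; they do not certify preprocessing choices on real cohorts.

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` use desk-scale versions of each
experiment, chosen to keep the whole validation run in minutes while leaving
the Monte-Carlo error well inside the asserted margins: 200 random graphs
(≤ 15 nodes) for the recursion oracle; 50 random 10×10×10 maps for the TFCE
oracle; 20 subjects for the stability claim; 50 white-noise subjects for FDR
calibration; 200 null cohorts (8×8×8 grid, n = 16) × 500 permutations for
FWE calibration; one planted cohort of n = 56 plus matched null runs
(500 permutations) for recovery; and n = 28 converter cohorts with 2000
bootstrap replicates for the ROC analyses.

## Known limitations

- Edge p-values ignore filtering-induced autocorrelation (documented above).
- The recursion's l ≥ 3 asymmetry means "seed-to-voxel" and "voxel-to-seed"
  readings differ slightly; we follow the seed-as-row convention.
- In-sample AUCs on 28 subjects are optimistic; use `cv="loo"` for honest
  numbers.
- TFCE parameters (H, E, dh, connectivity) are the standard volumetric
  defaults; the original analyses' toolbox does not expose its exact values,
  so these are a documented stand-in.
- Whether group analyses should z-score subject maps before contrast is
  ambiguous in the field; maps enter raw by default (config option).
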