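# Methods

## The analysis model

A striatal voxel's relationship to frontal cortex is summarised by its
connectivity fingerprint: the vector of Fisher-Z-transformed partial
correlations between the voxel's BOLD series and the mean series of each
of T frontal target ROIs. Group comparisons are made fingerprint-wise,
voxel by voxel, along three deliberately dissociable axes:

* **Aggregate divergence** `AD(a,b) = Σ |aᵢ − bᵢ|` — the cumulative
  strength change across matched connections. Defined as the sum of
  element-wise absolute differences rather than `|Σ(aᵢ − bᵢ)|`, which
  would let opposite-signed changes cancel and miss reconfigurations
  that leave net strength unchanged.
* **Rank order misarrangement** `ROM(a,b) = Σ |rank_a(i) − rank_b(i)|`
  — the Spearman footrule distance between the strength rank vectors.
  Rank 1 is the weakest connection; ties break deterministically to the
  lower target index. ROM is invariant to any strictly monotone
  transform of either profile, always an even integer, and
  bounded by T²/2 (450 at T = 30, attained by order reversal).
* **Entropy shift** `ES(a,b) = |H(a) − H(b)|` with
  `H(z) = −Σ pᵢ ln pᵢ`, `pᵢ = |zᵢ| / Σ|zⱼ|` — the change in how
  strength is concentrated versus dispersed. Natural log by default;
  the base and the absolute-value rectification are configurable
  because different conventions exist and the choice does not affect
  which voxels are flagged (ES scales monotonically with base).

A global additive offset moves AD but not ROM; permuting equal-magnitude
values moves ROM but neither the value multiset (hence not ES) nor the
expectation of AD under symmetric noise; a concentration change with
fixed ordering moves ES but not ROM. These constructions are asserted in
the test suite.

## From BOLD to fingerprints

The pipeline ingests *already preprocessed* volumes (motion-corrected,
normalised, smoothed, band-passed upstream) plus per-frame confounds.

1. **Censoring.** Frames with framewise displacement (FD) > 0.5 mm, the
   frame immediately preceding each, and the first 3 frames of a run are
   removed. Sessions with more than 25% of frames censored (strict
   inequality) are excluded. All four numbers are configurable.
2. **Nuisance GLM.** 6 motion parameters + their 6 temporal derivatives
   + mean white-matter + mean CSF signals + a polynomial trend basis of
   order 2 — 17 regressors with the defaults. The trend basis is built
   by QR orthogonalisation over the *retained* frames (a discrete
   Legendre-style basis), so its columns stay exactly orthogonal after
   censoring. Censored frames are dropped, not interpolated.
3. **Seed connectivity.** One model per target seed. The GLM output is
   computed as a partial correlation: voxel and seed series are both
   residualised on the nuisance matrix and the Pearson correlation of
   the residuals is taken. This is the standardised GLM coefficient,
   guaranteed to lie in [−1, 1] so the Fisher transform is defined;
   |r| ≥ 1 − 1e−7 is clipped with a warning. The seed series is the
   unweighted mean over target-mask voxels.
4. **FD adjustment.** Because residual head motion can differ between
   groups, each voxel-by-target Z cell is regressed across sessions on
   mean-centred subject mean FD and replaced by residual + intercept
   (the value expected at the grand-mean FD). This preserves every
   cell's cross-session mean exactly and removes the linear FD
   association. It is implemented as an isolated, swappable step; a
   per-session covariate in the group model would be a drop-in
   alternative. Empirical and normative sets are adjusted separately,
   each within itself.

Voxel ordering everywhere follows the striatal mask's lexicographic
(x, y, z) voxel order; persisted fingerprints carry an index checksum
that is verified on load.

## Normative null model

Observed metric values need a reference distribution for "how large is
large" in the absence of a group difference. A normative cohort matched
to the empirical sample (size, demographics, motion) is repeatedly split
— without replacement, independent draws per permutation — into
pseudo-groups of the empirical group sizes. Pseudo-group-average
fingerprint maps give a voxel-wise metric map per permutation; values
are pooled across voxels and permutations into a single per-metric null
(one scalar threshold per metric; a per-voxel mode exists behind a
flag). Significance everywhere uses the `value ≥ threshold` rule.

**Threshold convention.** The threshold is the empirical (1 − α)
quantile in the permutation-test sense: the support value whose null
exceedance under the ≥ rule is closest to α on a log scale. For a
continuous metric this is the usual upper order statistic; for the
integer-valued footrule it selects the best-calibrated achievable atom —
a plain interpolated quantile combined with either a strict or a
non-strict rule drives the realised exceedance an order of magnitude off
α whenever the quantile lands on a tie.

**Cluster extent.** Per permutation, the pseudo-group metric map is
thresholded and the maximum connected-component size recorded
(6-connectivity by default; 18/26 available). The extent threshold k is
the smallest size whose null exceedance fraction is below α_FWE = 0.05.
The empirical stage applies the printed-style strict rule "size > k−1",
identical to "size ≥ k". A permutation cluster null is used instead of
Gaussian-autocorrelation simulation: it needs no external software and
is exact under exchangeability of the normative sample.

**Calibration accounting.** When calibration is verified on fresh
permutations, the Monte-Carlo error of the exceedance rate is *not* the
naive binomial SE over pooled voxel-by-permutation samples: null values
within one permutation share the pseudo-group split and the session time
series, and the threshold itself is estimated from finitely many
permutations. `nullmodel.calibration_check` therefore combines a
cluster-robust (permutation-level) SE of the fresh rate with a cluster
bootstrap of the threshold over build permutations. With independent
samples this reduces to the naive binomial SE.

## Inference stages

* **Group comparisons** — smoker-sated and smoker-abstinent group-average
  fingerprints are each compared to the nonsmoker average; per metric,
  voxels at or above the null threshold form clusters filtered by the
  extent rule. Peaks are reported in world mm via the affine; ties break
  to the lowest lexicographic voxel index. No cross-metric
  multiple-comparison correction is applied — each metric is thresholded
  against its own null, and cross-metric mask overlap is itself one of
  the reported outcomes.
* **Within-subject state contrast** — each smoker's per-state fingerprints
  are scored against the nonsmoker average, giving subject-level metric
  maps; abstinent minus sated maps are tested with a voxel-wise paired
  t-test (two-sided; zero-variance voxels skipped with a warning),
  thresholded at p < 0.001 with the same extent rule.
* **Per-target rank differences** — at a voxel or cluster profile, a
  target's rank difference between groups is flagged when |Δrank| is
  strictly greater than 5 *and* at least the (1 − α) quantile of its
  permutation null (per-target |Δrank| under pseudo-group splits of the
  normative pool — the null the permutation machinery already provides,
  since no separate recipe exists for this test).
* **Demographics** — two-sample t for continuous variables, Pearson
  chi-square without continuity correction for categorical ones.
* **Brain–behaviour** — subject-level metric magnitudes are averaged over
  a significance-mask cluster (the AD∩ROM overlap cluster of the
  abstinent comparison when non-empty, else the largest AD cluster) and
  regressed on severity scores with age, sex (coded 0/1) and education as
  covariates. The interaction model adds AD×ROM after mean-centring both
  main effects; the highest-order term's t statistic is unaffected by the
  centring. Missing outcomes/predictors are dropped listwise; p-values
  are two-sided.

## The synthetic-data generator

The generator emulates the *statistical* structure the pipeline
consumes, not hemodynamics. Defaults define the study conditions at desk
scale: 20 two-session smokers and 15 nonsmokers (plus one high-motion
subject per group, generated to fail the censoring rule), a 35-subject
normative pool, a 12×12×12 grid with 3.4×3.4×4 mm voxels and a ~250-voxel
spherical "striatal" mask, T = 30 targets, 240-frame TR-2 s sessions
(8-minute scans).

**Signal model.** Target ROI series share a common band-limited
(0.01–0.1 Hz) component (pairwise correlation ≈ 0.35 — frontal ROIs
are strongly correlated in real data; strictly independent targets would
cap the achievable fingerprint spread far below what rank stability
requires). Each striatal voxel is a unit-variance linear mixture of the
shared component, the targets' unique components and a private part,
constructed so the voxel's structural correlations with the targets
follow a Fisher-Z ladder z_t = 0.15 + 0.014·t. The weakest targets carry
slightly negative unique-part weights — their positive overall
correlation rides on the shared component, as weak connections do in
real data. On top: 55% signal fraction (rest broadband noise),
per-(session, voxel) multiplicative gain jitter (sd 0.30, shared across
targets — aggregate-strength variability that leaves rank order intact),
per-cell weight jitter (sd 0.03), and a fixed per-voxel template jitter
(sd 0.01, shared by all subjects including the normative pool — real
fingerprints vary over the striatum).

**Planted effects**, in disjoint spherical regions, each scaled per
smoker by a severity modulator in [0.8, 1.2] that also drives the
generated FTND and withdrawal scores:

* gain ×(1 + 4) on all weights, abstinent session only → AD-type;
* reversal of the central 16 ranks of the ladder, both sessions
  (trait) → ROM-type (nominal footrule 128);
* temperature sharpening of the ladder with exponent 1.7, L1-normalised
  so total magnitude is preserved, abstinent only → ES-type.

**Motion.** Smooth parameter drift plus spike frames whose FD exceeds
0.5 mm; spikes carry large global artifacts (censoring has a real job)
and a subthreshold FD-proportional leak couples connectivity mildly to
motion level (FD adjustment has a real job). Ordinary subjects censor
3–15% of frames; high-motion subjects censor ~40% and are excluded,
so both outcomes of the exclusion rule occur in every default dataset.

**What the generator does not emulate** — hemodynamic response shape,
scanner-specific noise, anatomically shaped masks, spatial smoothness of
*between-subject* variability (subject-level fingerprint deviations are
independent across voxels; real deviations are spatially coherent, which
would require spatially-aware nulls), and session-order effects. Passing
validation therefore demonstrates correctness of the machinery and
internal calibration under exchangeability, not performance on real
cohorts.

## Numerical and design notes

* T = 30 targets (the scale of a bilateral frontal parcellation) is also
  what makes the footrule null well-behaved: with few targets its
  discrete support near the 0.999 quantile is too sparse to calibrate.
* Session length 240 frames: at half that, connectivity-estimate noise
  makes group-mean rank order too unstable for the rank metric at these
  group sizes.
* The concentration transform is L1-preserving so that a pure
  concentration change costs little aggregate divergence; the gain
  effect saturates in r (scaling weights cannot push a correlation past
  its structural ceiling), which bounds how strongly severity modulates
  subject-level AD.
* Degenerate inputs: all-zero profiles raise on entropy; zero FD
  variance makes FD adjustment an identity with a warning; rank-deficient
  nuisance or regression designs raise naming the offending columns;
  empty cluster tables are valid outputs.
* Reproducibility: every stochastic step draws from
  `numpy.random.default_rng` seeded from the config; rerunning a stage
  with the same config and inputs reproduces its outputs exactly.

## Validation suite

`cpa.validation.validate_default_scenario` generates the default
scenario, runs fingerprints → null → group maps → clusters, and measures:
(1) fresh-permutation exceedance of each derived threshold against α
within the combined Monte-Carlo SE described above; (2) the family-wise
error of the cluster rule on fresh permutations against α_FWE; (3)
sensitivity of each matched metric on its planted region, cross-metric
detection (expected lower than matched), and the state/trait pattern
(trait rank effects significant in both sessions, abstinent-only gain
effects only in the abstinent comparison). The acceptance script runs
the same procedure and reports the numbers; the test suite asserts them.
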