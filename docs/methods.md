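# Methods

`rscleanbench` compares four data-driven artifact-removal strategies for
resting-state fMRI — regression of the 24-parameter motion expansion
(MOTreg), motion plus WM/CSF mean-signal regression (MWCreg), and
ICA-component cleanup in its *soft* and *aggressive* forms — against an
uncleaned baseline, on synthetic two-group cohorts in which both the
connectivity effect of interest and every artifact source are known
exactly. This note records the models, the parameter choices, and the
numerical decisions; it is the place where open design questions were
settled.

## The synthetic cohort

The generator emulates a small clinical rsfMRI study: 20 healthy controls
(HC) and 21 patients (AD), 160 volumes at TR = 2.5 s, a 24 x 28 x 22 grid
of 3 mm voxels. The head is a nested-ellipsoid geometry (central
ventricular CSF, a WM shell, a cortical GM ribbon), and ten non-negative
Gaussian-blob network templates live in the ribbon. The default-mode
network (DMN, template 0) has two nodes; its posterior node is centred on
a 6 mm-radius posterior-cingulate seed sphere, which sits inside a larger
posterior-cortex ROI (the "PCC/precuneus" ROI used for the group test).

Each subject's 4D series is

```
data = baseline + sum_k map_k * tc_k + sum_j artifact_map_j * artifact_tc_j + noise
```

with a tissue-dependent positive baseline (~1000 units, so temporal SNR is
well defined), band-limited (0.01-0.1 Hz) unit-variance network
timecourses scaled by a per-subject log-normal gain (log-sd 0.15), and
i.i.d. Gaussian thermal noise (sd 1) inside the brain. The planted group
effect multiplies the **posterior DMN node** of AD subjects by
`dmn_deficit = 0.6`; everything else is identically distributed across
groups except where noted.

Artifact classes (default peak amplitudes in signal units):

| name | spatial support | timecourse | amplitude |
|---|---|---|---|
| motion_edge | one-voxel brain-boundary shell | exact linear mix of the subject's 24-parameter motion expansion | 3 |
| motion_global | smooth signed whole-brain gradient field | second linear mix of the same expansion | 3.5 |
| csf_pulsation | ventricular CSF only | band 0.06-0.19 Hz | 6 |
| wm_drift | WM shell | band 0.005-0.025 Hz | 4 |
| vessel | thin tube along y skirting the posterior node (crosses the posterior ROI) | band 0.07-0.19 Hz, correlation 0.3 with the subject's DMN timecourse | 16 |
| scanner_drift | whole brain | linear ramp + <0.01 Hz sine (removed by the high-pass) | 5 |

Per-subject artifact loads are log-normal (log-sd 0.5-0.8). Two choices
deserve explanation:

* **Motion waveform vs. motion load.** Motion traces are smooth random
  walks rescaled so that each subject's mean relative displacement matches
  a target drawn from the group law (HC 0.07 +/- 0.04 mm, AD
  0.09 +/- 0.06 mm). The *waveforms* of the two motion artifacts are exact
  linear functions of the 24-parameter expansion, so motion regression can
  remove them completely; their *loads* are i.i.d. log-normal
  susceptibility factors, identical in distribution across groups. When
  load was tied to displacement, the higher AD motion produced a
  systematic attenuation of AD connectivity estimates that made the
  *uncleaned* group test spuriously well powered — the opposite of the
  regime this benchmark is meant to probe, where artifact-driven
  between-subject variance hides a real deficit until it is removed.
* **Vessel-DMN coupling.** The vessel timecourse shares 30% correlation
  with the DMN timecourse (vascular fluctuations partially coupled to
  network BOLD). This puts genuinely shared variance between signal and
  noise components, which is exactly the quantity that distinguishes soft
  from aggressive cleanup.

Determinism: a master `numpy.random.SeedSequence` is spawned into
independent per-subject streams; identical `(config, seed)` reproduces the
cohort bit for bit.

The gray-matter-volume covariate is drawn from two Gaussians (HC
0.62 +/- 0.03, AD 0.55 +/- 0.04), emulating group atrophy without any
structural modelling; it feeds the permutation GLM as a nuisance
covariate.

## Preprocessing

Spatial smoothing uses an isotropic Gaussian (default FWHM 5 mm) with
reflecting boundaries, which conserves the within-volume sum. Temporal
high-pass filtering (default cutoff 0.01 Hz) is implemented as regression
on a DCT-II drift basis containing every component with frequency **at or
below** the cutoff — linear and exactly idempotent. (With only
strictly-below components, a 0.002 Hz drift retains ~12% of its amplitude;
including the at-cutoff component brings sub-cutoff residuals below 10%,
measured as sqrt(2) x RMS.) The voxelwise temporal mean is re-added after
filtering so temporal SNR stays defined.

## Cleanup variants

All confound columns are demeaned; each voxel's temporal mean is removed
before and restored after every regression, so means (hence tSNR
numerators) are identical across variants.

* `motreg`: OLS residualisation on the 24-parameter expansion (traces,
  backward differences, squares of both).
* `mwcreg`: the same design plus the mean signals of the (1-voxel-eroded)
  WM and ventricular ROIs. Because these regressors are re-derived from
  whatever data the cleanup is applied to, a second application removes
  further variance: `mwcreg` is the one variant that is not idempotent.
* `compsoft`: (1) residualise the data *and all component timecourses* on
  the motion expansion; (2) regress the data jointly on all component
  timecourses and subtract only the noise-labeled components' fitted
  contribution (their unique variance). Components whose timecourse is
  almost fully explained by motion (residual sd < 5% of original) are
  dropped from the joint fit — their column is numerically null and would
  otherwise make the joint design singular; the joint fit uses a
  pseudoinverse with a relative singular-value cutoff of 1e-3.
* `compagg`: OLS residualisation on motion plus the noise-labeled
  component timecourses together (full variance).

Exact consequences used as tests: per-voxel residual temporal variance
obeys `uncleaned >= motreg >= mwcreg` (nested designs) and
`compsoft >= compagg` (the aggressive residual is the orthogonal
projection, the minimum over everything soft can produce). The analogous
*pointwise* ordering of the %dSTD maps — "aggressive removes at least as
large a fluctuation at every voxel" — is **not** a theorem and fails in
practice: the soft subtraction is a joint-fit contribution, not a
projection, and when component timecourses are correlated, suppression
effects let it exceed the aggressive removal at individual voxels. Only
the variance ordering is asserted.

## ICA and labeling

Single-subject spatial ICA = voxelwise-demeaned data, PCA reduction,
FastICA (scikit-learn, logcosh, tol 1e-3, up to 5000 iterations, up to
five seeded restarts before a convergence error). The pipeline wrapper
handles stubborn subjects by first relaxing the tolerance at the
requested model order and only then reducing the order: an
under-decomposed subject can retain an entire artifact source and become
a group-level outlier, while a looser tolerance at full order costs
little separation quality. Components are ordered
by explained variance and sign-fixed to non-negative spatial skewness.
Dimensionality: the benchmark pipeline uses a fixed model order of 16. A
90%-variance criterion (available as `n_components="auto"`) selects only
4-7 components on these cohorts because the artifacts dominate total
variance; at that order artifact and network sources mix, and removing
mixed components removes network signal with them. Fixed order 16 is the
analogue of the generous model orders automatic dimensionality estimation
produces on real data.

Labeling is the simulation-mode oracle (spatial correlation against the
planted artifact and template maps, threshold 0.4) or a rule-based
surrogate with five rules: top-weight mass in the boundary shell, in CSF,
or in WM above 0.5; high-frequency (>0.1 Hz) power fraction above 0.5; or
small-sample-adjusted multiple correlation with the motion-expansion
design above 0.6. The WM rule was added because a WM-confined drift
component triggers none of the other four; the motion rule uses the
*multiple* correlation (adjusted for the chance fit of 24 regressors on a
short series) because planted motion components are mixes of many columns
and never correlate strongly with any single one.

## Connectivity, metrics, statistics

Seed-based maps: Pearson correlation of every brain voxel with the
seed-sphere mean series, Fisher r-to-z with r clamped to +/-(1 - 1e-7);
zero-variance voxels get z = 0 and are counted. Dual regression: stage 1
regresses each volume on all templates simultaneously (templates demeaned
and variance-normalised across brain voxels, intercept included); stage 2
regresses each voxel's series on the demeaned stage-1 timecourses. The
DMN map is selected by its known template index.

Temporal SNR = temporal mean / temporal SD (ddof 1), median within a
2-iteration-eroded brain mask. %dSTD follows
`100 * STD_t(uncleaned - cleaned) / STD_t(uncleaned)` — the equation form,
not the loose "difference of the STD images" paraphrase sometimes used to
describe it. Consistency maps are across-subject sample SDs of the z/PE
maps; they are compared with a voxelwise paired t-test whose degrees of
freedom ignore spatial autocorrelation (a deliberate replication of common
practice; its p-values are descriptive).

Group inference: pooled-variance two-sample t-tests (the pooled form,
not Welch, reproduces the reference ROI t-statistics from their reported
group summaries); a voxelwise GLM
`y = b0 + b1*group + b2*gm_volume` tested by Freedman-Lane permutation of
reduced-model residuals (seeded, default 1000 permutations; a covariate
collinear with the group model is dropped with a warning), with
cluster-extent correction: two-tailed primary threshold at p = 0.05,
26-connected clusters, corrected p = (1 + #{max-size* >= size}) /
(1 + n_perm).

## Replicate experiments and problem sizes

`rscleanbench.validation` packages two experiments:

* **Power**: 50 replicate cohorts on a 20 x 24 x 18 grid with 120 volumes
  (full 20 + 21 subjects, default amplitudes and deficit, ICA order 16),
  measuring the one-sided detection rate of the planted deficit by the
  posterior-ROI dual-regression t-test at alpha = 0.05. The reduced grid
  keeps 50 replicates to a few minutes on one CPU; below roughly this size
  single-subject ICA stops separating the planted sources, so further
  shrinking would measure ICA failure rather than cleanup quality.
* **Calibration**: 200 null cohorts of i.i.d. Gaussian statistic maps
  (6 x 8 x 5 grid, group-dependent covariate, 199 permutations),
  measuring the voxel-level rejection rate at p <= 0.05 and the
  cluster-level family-wise error rate against 95% binomial intervals
  around the nominal level.

## What the simulation does and does not show

The generator reproduces the *structure* of the comparison — nested
confound designs, separable artifact sources with known supports, a
localized group deficit masked by artifact-driven between-subject
variance — but not real data's spatial autocorrelation of noise,
registration error, susceptibility dropout, non-Gaussian physiology, or
the true difficulty of classifying borderline components. Passing the
battery therefore demonstrates that the pipeline's mathematics and
orderings behave as designed, not that any particular cleanup is superior
on real scanner data. Known limitations: the ellipsoid anatomy makes
tissue ROIs unrealistically clean; the ground-truth labeler sees the
planted maps, so its errors only reflect ICA mixing; and the consistency
comparison aggregates the two groups' map SDs, since per-group orderings
at a single simulated cohort fluctuate with the draw.
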