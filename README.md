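# rscleanbench

Benchmark of data-driven artifact-removal strategies for resting-state
fMRI, evaluated on synthetic two-group cohorts with known ground truth.

Cleaning resting-state data is a prerequisite for clinical functional
connectivity (FC) studies: head motion, CSF pulsation, vessel signals,
WM and scanner drifts all add between-subject variability that can hide a
real group difference at clinical sample sizes. This package implements
the standard ladder of data-driven cleanups and the evaluation battery
used to compare them, and — because clinical data cannot ship with code —
a cohort simulator in which the "disease effect" (a reduced posterior
default-mode-network coupling) and every artifact source are planted and
therefore known exactly. It is aimed at methods researchers who want a
fully controlled testbed for confound-regression and ICA-denoising
pipelines.

## What it implements

Five datasets per subject, after shared smoothing (5 mm FWHM) and 0.01 Hz
high-pass filtering:

1. **uncleaned** — preprocessing only;
2. **MOTreg** — OLS removal of the 24-parameter motion expansion
   (6 rigid-body traces, backward differences, squares of the 12);
3. **MWCreg** — motion expansion + WM and CSF mean signals;
4. **soft ICA cleanup** — full motion removal, then joint regression on
   all spatial-ICA component timecourses with subtraction of only the
   noise components' unique variance;
5. **aggressive ICA cleanup** — full removal of motion and the noise
   components' entire variance.

Evaluation: temporal SNR (median over an eroded brain mask), voxelwise
%dSTD suppression maps `100*STD_t(uncl-clean)/STD_t(uncl)` with >25%
exceedance probability maps, within-group consistency (across-subject SD
of FC maps) with paired-t comparisons, and between-group inference on two
FC estimators (PCC-seed correlation with Fisher r-to-z, and template-based
dual regression), via ROI-level pooled two-sample t-tests and a voxelwise
Freedman-Lane permutation GLM with a gray-matter-volume covariate and
cluster-extent correction.

The ROI group test uses the pooled-variance two-sample t

    t = (m_HC - m_AD) / (s_p * sqrt(1/n_HC + 1/n_AD)),
    s_p^2 = ((n_HC-1) s_HC^2 + (n_AD-1) s_AD^2) / (n_HC + n_AD - 2)

which reproduces the reference ROI statistics of the clinical comparison
study this benchmark emulates, directly from its reported group means and
SDs (see the worked example).

## Worked example

```python
from rscleanbench import SummaryStats, two_sample_t_summary

# posterior-ROI dual-regression parameter estimates, printed group summaries
hc = SummaryStats(mean=10.639, sd=2.493, n=20)
ad = SummaryStats(mean=8.117, sd=2.527, n=21)
t, df, p = two_sample_t_summary(hc, ad)
print(f"t({df}) = {t:.3f}, p = {p:.3f}")
```

prints

```
t(39) = 3.215, p = 0.003
```

— with aggressive ICA cleanup the patient group's posterior-DMN coupling
is significantly lower, while the same test on the uncleaned summaries
(17.640 +/- 10.337 vs 19.588 +/- 11.971) gives t(39) = -0.556, p = 0.581:
the deficit is invisible before cleaning.

Simulation in three lines:

```python
from rscleanbench import SimulationConfig, generate_cohort
from rscleanbench.pipeline import analyze_cohort, roi_group_table

cohort, truth = generate_cohort(SimulationConfig(random_seed=0))
analysis = analyze_cohort(cohort, truth)
print(roi_group_table(analysis))   # per (method, cleanup): group means, SDs, t, p
```

On the default cohort this table shows the planted deficit undetected in
the uncleaned data and strongly detected (t > 8 seed-based, t > 14
dual-regression) after aggressive component cleanup.

A `rscleanbench` command-line tool exposes the stages (`simulate`,
`preprocess`, `ica`, `clean`, `fc`, `evaluate`, `report`) for NIfTI data
on disk; `rscleanbench report --seed 0 --out bench_out` runs the whole
comparison and writes the report tables.

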