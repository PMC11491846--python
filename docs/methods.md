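# Methods

`cravedecode` is a simulator-backed re-implementation of a classifier-based
real-time fMRI neurofeedback (rtfMRI-NF) analysis for smoking craving.  No
human data ship with the package: every stage is exercised on synthetic
cohorts whose generative structure mirrors the statistical assumptions of
the analysis, so recovery, calibration and arithmetic properties can be
checked end to end on a desktop.

## Generative model

A session has three runs: one no-feedback run (6 crave + 6 don't-crave
blocks of 34–46 s, 13 fixation blocks of 12–16 s, exactly 684 s) and two
feedback runs (7 + 7 task blocks of 28–46 s, 15 fixations of 12–16 s,
exactly 768 s), sampled on a TR = 2 s grid.  Jittered durations are drawn
uniformly on the TR grid and a residual-redistribution repair (±TR steps on
randomly chosen blocks, respecting each range) enforces the exact run
total; the condition order is a constrained shuffle with at most two
consecutive same-condition blocks, fixation first and last.  The literature
sometimes implies a fixed per-condition volume count; we do not enforce
one — sample counts follow from the jittered design.

Each subject `s` has a voxelwise discriminant pattern

    w_s = unit(rho * w_shared + (1 - rho) * w_unique,s),

with `rho` (the `shared_fraction`) interpolating between a cohort-shared and
a fully idiosyncratic pattern.  The voxel signal of run `r` is

    x_v(t) = baseline + A_r * w_s[v] * (h_crave(t) - h_nocrave(t))
             + drift + noise + motion coupling,

where `h_c` is the condition boxcar convolved with a canonical double-gamma
HRF (peak 6 s, undershoot 16 s, peak:undershoot ratio 6, kernel normalized
to unit integral so a sustained block plateaus at 1).  `A_r` is the per-run
effect amplitude — the generative handle for learning across repeated
feedback runs.  Drift is a second-order Legendre polynomial with random
per-voxel coefficients; noise is an equal-power mixture of AR(1)
(coefficient 0.3) and white Gaussian noise with total marginal SD
`noise_sd`; head motion is a bounded random walk (6 parameters) optionally
coupled into the data.  The default brain is a 12×12×10 grid with an
ellipsoidal mask (680 voxels) and a six-slab atlas whose posterior slab is
labelled `visual` for exclusion masking.

Defaults: `noise_sd = 2.0`, `run_amplitudes = (2.0, 2.5, 3.0)`.  These were
calibrated once so that individual-level condition decoding lands in the
high-80s/low-90s percent range typical of whole-brain craving decoding in
small cohorts, while the 1–3 amplitude range spans a non-saturated accuracy
band (~75% at amplitude 1 to ~90% at 3) — necessary for amplitude-recovery
experiments to be informative.

Behaviour: six smoking measures (cigarettes/day, use form, FTND, SJWS, CO
ppm, CO %Hb — the last two nearly collinear, as in practice) load on one
latent severity factor.  The latent factor can be tied to the subjects' ROI
pattern strength with a configurable correlation, or (per-run coupling) to
multiplicative ROI gains, emulating brain–behaviour coupling that changes
over neurofeedback training.

What the simulator does **not** emulate: spatial autocorrelation and
physiological (cardiac/respiratory) noise, slice-timing effects, realistic
anatomy or atlas registration, and scanner drift nonstationarity.  Passing
tests therefore demonstrate correctness and calibration of the *analysis
machinery* under the stated generative assumptions, not performance claims
about real BOLD data.

## Online feedback loop

The online decoder is a linear SVM with C = 200 trained on the prior run's
task volumes, excluding the first two volumes of every block (HRF rise).
The per-voxel training-run mean is removed before fitting and stored in the
model; streamed volumes receive the identical offset removal.  This is the
offset conditioning any real-time decoder performs — raw BOLD sits on a
large common baseline that would otherwise dominate the kernel.

Each streamed task volume yields a signed hyperplane distance `d`; a causal
prefix-OLS line (all distances observed so far in the run) is subtracted to
remove drift and offset; |d̃| is discretized with half-open, lower-inclusive
bins at 0.2/0.4/0.6/0.8 (bin 0 is a dead zone, bin 4 the "ideal" bin); the
slider integrates `sign(d̃) · (bin/4) / L` per volume, where `L` is the
block length in volumes, so sustained bin-4 feedback of the correct sign
reaches the endpoint exactly at block end.  The slider resets at every
task-block onset, and feedback is withheld (slider frozen) during the first
crave and first don't-crave blocks.  Fixation volumes emit nothing.

Design choices made where the procedure was genuinely open: the distance
detrend is a causal prefix regression restarted per run (a rolling window is
a config alternative); bin boundaries are lower-inclusive; the linear
bin-to-step mapping is the minimal choice making bin 4 exactly reach the
endpoint.

## Offline preprocessing

Temporal smoothing is a centered 3-volume moving average with truncated,
renormalized edge windows (no boundary attenuation; constants are
preserved).  Detrending removes a least-squares polynomial (default linear)
but *keeps the voxel mean*.  Percent signal change is then referenced to
the rest baseline: the voxel's mean over volumes where the HRF-convolved
all-task regressor is ≤ 0 (the fixation state).  Referencing to rest rather
than the run mean matters: a run-mean reference forces each voxel's samples
to sum to zero, which makes held-out fold means anti-correlate with
training-fold means and drives cross-validated accuracy *below* chance on
null data.  Non-positive-baseline voxels are flagged and dropped from the
mask.

A note on edge handling: smoothing and detrending commute exactly for
signals that vanish near the run boundaries, but a linear ramp is slightly
distorted by the truncated edge windows, which perturbs the fitted trend by
O(1/n); the discrepancy between the two operation orders is a small
fitted-line difference, not an interior artifact.

Group-level features are per-block GLM betas: one HRF-convolved regressor
per task block plus intercept and linear-trend nuisance columns
(near-orthogonal safeguards, switchable off), condition-level beta = mean
of the condition's block betas.  Framewise displacement follows the
rigid-body convention FD(t) = Σ|Δtrans| + 50 mm · Σ|Δrot|.  Automasking
thresholds the mean image at a configurable fraction (default 0.5) of a
robust peak (98th percentile) and keeps the largest 6-connected component.

## Classification framework

Individual-level decoding uses volume-wise PSC samples (first two volumes
of each block dropped; the first crave/don't-crave block pair of feedback
runs excluded); group-level decoding uses per-subject condition beta maps,
folded by subject so no subject straddles the train/test boundary.  Scaling
is global min–max — a single (min, max) over the entire training matrix,
voxels × samples jointly — fitted on training folds only and applied
unchanged to validation/test data (out-of-range values allowed).

Folds: samples are shuffled into 10 near-equal folds (sizes differing by at
most one); the test fold is drawn from the largest folds and validation
from the next largest, reproducing the canonical counts 114/15/15 for 144
samples and 24/3/4 for 31 subjects.  Per repeat the partition is
re-shuffled (defaults: 20 repeats individual, 100 group).  The ν-SVM grid
(0.1–0.8, step 0.1) is selected on the validation fold; infeasible ν values
(class-balance dependent) are skipped with a log note.  A fixed-C SVM
(C = 200) runs the same scheme for the online-vs-offline comparison.  After
cross-validation the model is refit on all samples with the modal selected
hyperparameter; that model supplies retest transfers and the weight map for
group inference.

Volume-wise random folds plus temporal smoothing share smoothed noise
between temporally adjacent train and test volumes; on synthetic data this
saturates accuracy regardless of SNR.  The faithful volume-wise folds are
kept as the default, and `psc_samples(..., thin=3)` (stride equal to the
smoothing window) provides decorrelated samples for recovery experiments
where accuracy must reflect the evoked pattern.  Run-pair contrasts balance
class sizes by seeded subsampling of the longer run.

The nine run-pair contrasts (3 run pairs × {collapsed, crave-only,
nocrave-only}) force the visual-exclusion mask; condition contrasts use the
whole brain.  Post-hoc statistics: paired t (individual, per-subject
vectors) or two-sample t (group, per-repeat vectors) with Bonferroni
correction by the stated sample counts, plus an OLS trend test across the
ordered contrasts; motion checks are a paired condition t on mean FD and an
OLS of accuracy on the FD difference.

## Group inference

Weight maps are pseudo z-scored (in-mask mean 0, SD 1; population-SD
convention).  Voxelwise statistics: one-sample t against zero (df = n − 1;
zero-variance voxels get ±inf sentinels) and one-way repeated-measures
ANOVA with run as the within-subject factor (df = (2, 2(n − 1));
subject-constant offsets absorbed by blocking; a relative-tolerance guard
reports F = 0 for exactly degenerate voxels).  Family-wise correction uses
a max-statistic permutation null — sign flips of whole subject maps for the
t, independent within-subject run-label permutations for the ANOVA — with
p = (1 + #{perm max ≥ observed}) / (1 + n_perm); Bonferroni of the
per-voxel permutation p is a config alternative.  Defaults: 10 000
permutations; the one-sample t is two-sided.  ROIs are 6-connected
components of the significance mask, size-filtered (default min extent 3
voxels) and labelled by atlas majority.

## Brain–behaviour associations

The severity score is the first principal component of the z-scored
smoking measures (rows with missing values dropped; constant columns
dropped with a log; sign fixed so the cigarettes/day loading is positive).
Outliers are flagged at 2.5 robust SDs (1.4826 × MAD) in either variable
and removed listwise; zero MAD flags nothing, with a warning.  Per ROI and
run, the ROI-mean weight is regressed on the score; significance is a
two-sided permutation p on |r| (10 000 shuffles, +1-corrected) and the 95%
CI a percentile bootstrap (10 000 resamples).  Heterogeneity of the three
per-run correlations is Cochran's Q on Fisher-z transformed coefficients
with weights n − 3, chi-square df = 2 under homogeneity.

## Numerical choices and reference solvers

SVM fits use libsvm (scikit-learn) with tolerance 1e-6.  The package also
carries independent quadratic-programming reference solvers (multi-start
SLSQP on the C-SVM dual and the ν-SVM dual, each followed by an active-set
KKT polish) used only to cross-check the production path; ν-SVM decision
values are compared after libsvm's margin rescaling by ρ.  The comparison
uses cleanly separable toys: with overlapping classes the ν-SVM margin
collapses and libsvm's dual stopping rule caps its attainable decision
precision near 1e-4, so no solver pair is comparable there.

Reproducibility: every generator and experiment is a pure function of its
parameters and a seed; the pipeline derives per-stage child seeds from a
single master seed via a documented CRC32/SeedSequence scheme and records
them in a manifest.

## Problem sizes in the validation suite

The validation suite and the reproduction script run the recovery
experiments at desk scale: 8-subject cohorts on the default 680-voxel
brain, 20 simulation seeds per claim, 2 CV repeats per subject (8 for the
group level), 500-permutation nulls over 50 cohorts, and 1000-shuffle
association nulls over 100 simulated datasets.  These sizes give the
claimed checks adequate power while keeping a full run in minutes on one
CPU; all counts are parameters, and the canonical constants (20/100
repeats, 10 000 permutations and bootstraps) remain the library defaults.

## Known limitations

* Sample counts per condition follow the jittered designs and differ
  slightly between runs; run-pair contrasts subsample to balance.
* The headline accuracies of whole-brain craving decoding in real cohorts
  depend on temporal autocorrelation that volume-wise folds do not control;
  the simulator makes this explicit (see the thinning note above) rather
  than hiding it.
* ROI labels come from the synthetic slab atlas; no anatomical lookup is
  provided.
* The ANOVA permutation loop is O(n_perm · n · V) without vectorization
  across permutations; at 10 000 permutations on large grids it is the
  slowest stage.
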