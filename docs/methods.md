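# Methods

`pdcnet` implements a source-level resting-state EEG analysis for stroke
rehabilitation cohorts: directed functional connectivity by partial directed
coherence (PDC) on LCMV-beamformed virtual channels, data-driven network
thresholding by orthogonal minimum spanning trees (OMST), graph metrics and
a hemispheric laterality index, normality-gated group statistics, and
band-wise RBF-SVM classification under leave-one-subject-out
cross-validation. Because the clinical recordings such a study rests on are
not redistributable, the package ships a first-class synthetic cohort
generator with known directed ground truth; every quantitative claim the
test suite makes is made against that ground truth or against the published
clinical score table that is packaged as a fixture.

## Analysis model

**MVAR/PDC.** Each subject's epoched source array (28 regions x 2000
samples x 29 epochs at 500 Hz) is modelled by a single multivariate
autoregressive (MVAR) process of order p, fitted by least squares pooled
across epochs; lagged predictors never cross an epoch boundary. With
coefficient matrices A_1..A_p, the frequency-domain coefficient matrix is

    Abar(f) = I - sum_r A_r exp(-i 2 pi f r / fs),

and the (magnitude) partial directed coherence from region j to region i is

    pi_ij(f) = |Abar_ij(f)| / sqrt(sum_k |Abar_kj(f)|^2),

so the squared outflows of each source column sum to one at every
frequency. PDC is evaluated on a 0.5 Hz grid from 1 to 50 Hz and averaged
over the half-open band intervals delta 1-4, theta 4-8, alpha 8-13, beta
13-30 and gamma 30-50 Hz (the conventional 0.1 Hz lower delta edge is
raised to 1 Hz because the broadband high-pass has already removed slower
content). The band matrices have zero diagonal and entry (i, j) quantifies
flow from column j to row i.

One pooled broadband fit feeds all five bands. Fitting separate MVAR models
to narrowband-filtered data is deliberately avoided: narrowband filtering
makes the lagged regressors nearly deterministic and the AR estimate
ill-posed. A squared-PDC variant is available by configuration
(`pdc_squared`).

**Model order.** The default order is 5. BIC-based selection over 2..10
(`mvar_order: auto`) is implemented and tested — on noise-free AR data it
recovers the true order — but under sensor noise and beamformer mixing the
true process is no longer finite-order and BIC drifts to the cap, at about
five times the runtime, so the fixed default is used for routine runs.

**Estimation conditioning.** EEG rhythms live far below the 250 Hz Nyquist
frequency, so adjacent lags are highly correlated and the lagged design is
close to collinear (condition numbers around 1e7). All solves therefore go
through SVD/QR factorizations rather than normal equations, with a hard
failure above condition 1e10.

**Beamforming.** The scalar linearly constrained minimum variance filter
per source j is w_j = (l_j' C^-1 l_j)^-1 l_j' C^-1 with
C regularized by 5% of the mean sensor variance (C + 0.05 mean(diag C) I).
Each filter has unit gain on its own leadfield column (checked to 1e-8).
The pipeline applies the same common-average projection to the leadfield
columns that preprocessing applied to the data, keeping the forward model
consistent with the recording reference. SVD parcel reduction (dominant
left-singular-vector time course, sign-aligned with the constituent mean)
is part of the localization stage; with the one-column-per-region synthetic
leadfields it reduces to a pass-through.

**OMST thresholding.** Directed band matrices are symmetrized by the mean
of the two directions, mapped to distances 1/w, and successive
edge-disjoint minimum spanning trees are aggregated. After each round the
global cost-efficiency J = E_glob(selected)/E_glob(full) - cost is
recorded, where cost is the selected fraction of total weight; aggregation
stops at R-1 rounds, on disconnection of the remaining graph, or after
three consecutive declines in J, and the J-maximizing aggregation is kept.
Direction is then restored: a directed edge survives if its undirected
edge was selected and its directed weight is positive. Node strength and
weighted local efficiency are computed on the OMST-masked weighted matrix,
degree on its boolean support (configurable interpretations are noted in
the code).

**Laterality.** After hemisphere flipping the affected hemisphere is
canonically LEFT. For each of the 14 homotopic base regions,
LI = (U - A)/(U + A) on the out-strength of the unaffected (right) and
affected (left) homotope; pairs with U + A = 0 are flagged undefined and
excluded. The group-level test of mean LI against zero uses a t-test when
Shapiro-Wilk does not reject normality at 0.05 and the Wilcoxon signed-rank
test otherwise; a zero-variance sample with non-zero constant is treated
as significant by construction (degenerate case, flagged).

**Group statistics.** Within-group comparisons are two-sided paired t
tests, across-group comparisons two-sided unpaired t tests, each behind
the same Shapiro-Wilk gate (fallbacks: signed-rank / Mann-Whitney).
Connectivity contrasts declare significance at a fixed alpha of 0.01 — a
modified-Bonferroni allowance for the three planned comparisons (post vs
pre, control vs pre, control vs post) — with Cohen's d reported throughout
(paired: mean difference over SD of differences with n-1; unpaired:
pooled-SD). The clinical motor-score table (Fugl-Meyer lower-extremity
motor domain, 34 points, 22 patients in two rehabilitation arms) ships as
a CSV fixture; its summary, a two-way mixed (split-plot) ANOVA
(group x time, via pingouin behind the module surface), and the
Delta-FMA vs Delta-connectivity Pearson correlation are computed from it.

**Classification.** Band matrices are flattened to 756 off-diagonal
features. The outer loop leaves one SUBJECT out (both sessions together in
the pre-vs-post comparison, which prevents identity leakage; a sample-wise
variant exists behind `subject_wise=False`). Inside each outer fold only:
z-score normalization (train statistics applied to the held-out sample;
zero-variance columns centred, not divided), ReliefF ranking (k=3
neighbours, range-normalized differences, deterministic full pass), and a
5-fold grid search over C in {0.1, 1, 10}, kernel scale in
{0.01, 0.1, 1, auto} and the number of retained top-ranked features in
{20, 50, 100}. "Kernel scale" s follows the divisor convention
(gamma = 1/s^2); "auto" is gamma = 1/(n_features * variance). With
z-scored features the numeric scales produce nearly degenerate kernels and
the inner search selects "auto", consistent with that convention being the
operating point of such pipelines. Accuracy, sensitivity, specificity and
ROC-AUC (from pooled decision values) are reported on the 0-100 scale.

## The synthetic cohort generator

The generator emulates the study conditions: 22 subjects per cohort
(healthy control, stroke pre-intervention, stroke post-intervention),
3-minute recordings at 500 Hz, 64 sensors, and an 11/11 left/right lesion
split. Stroke subjects keep the same per-subject coupling jitter
(lognormal, sigma = 0.1 on each region's outgoing weights) across their
paired pre/post sessions, so session differences reflect only the
condition change.

**Dynamics.** Each of the 28 regions is a damped AR(2) oscillator whose
resonance sits inside one of the five bands (bands cycle over the 14
homotopic pairs; regions sharing a band are detuned within it). Pole radii
are band-dependent (0.80 delta to 0.95 gamma, roughly constant Q): at 500
Hz all EEG rhythms sit near z = 1, and sharper low-frequency poles would
make the variance-equalized innovations so small that the lagged design
loses identifiability. Directed couplings form a feed-forward DAG over a
fixed region ranking (the regions carrying cohort effects — SMA, dorsalA6,
M1, PoG, INS, vPM — rank first so they all have outflow): with an acyclic
coupling graph the MVAR eigenvalues are exactly the diagonal oscillator
poles, so every template and every jittered subject system is stable by
construction. Couplings only target alpha/beta/gamma regions (slow
resonances would amplify any broadband inflow by the inverse of their tiny
characteristic-polynomial magnitude, by factors in the hundreds); each
weight is sized in units of the target's own resonance magnitude
(strength 4.0, i.e. a bounded per-hop transfer gain), and each edge is
tagged with its source region's band — the frequency at which its PDC
concentrates. Innovation variances are equalized by a fixed-point
iteration on the companion-form discrete Lyapunov equation so regional
amplitudes are comparable (as in broadband-normalized EEG), with a minimum
innovation share of 1% of the marginal variance as an identifiability
guard.

**Cohort effects** (multiplicative on the targeted regions' outgoing
template weights, mirrored for right-side lesions):

* stroke-pre vs HC: affected SMA x0.6, unaffected vPM x0.6, affected INS
  x1.4, affected dorsalA6 x1.4;
* stroke-post vs stroke-pre: unaffected M1 x1.4, affected PoG x1.4.

The HC template is exactly hemisphere-symmetric (edges drawn for the left
hemisphere and mirrored with identical weights).

**Forward model and noise.** The leadfield is a random orthonormal frame
in sensor space with unit-norm columns — a geometric surrogate with
well-separated sources and no head-model physics (an optional coherence
parameter blends in mutual correlation). Sensor noise is spatially white
Gaussian at 20 dB total-signal-to-noise, representing clean active-
electrode resting recordings (artifact generation and removal are out of
scope, so the synthetic data corresponds to the post-artifact-cleaning
stage of a real pipeline).

**What passing tests do and do not show.** The generator provides a ground
truth with band-specific directed edges, realistic sample sizes and a
plausible signal chain (forward projection, sensor noise, re-referencing,
beamforming). It does not emulate volume-conduction geometry, 1/f
background spectra, non-Gaussian or nonstationary dynamics, artifacts, or
feedback loops between regions. Edge-recovery and classification results
on it therefore demonstrate that the implementation is correct and that
the method behaves as designed under its own assumptions — not that the
same performance would be obtained on clinical recordings.

## Evaluation conventions

Edge recovery is scored on the group-mean band matrices of the control
cohort: within each band, positives are the generator's edges tagged with
that band, negatives are directed pairs carrying no edge in any band
(pairs with an edge of another band are excluded — their flow is real,
only at another frequency), and the ROC-AUC is pooled over the five bands.
Classification benchmarks use the alpha band, where the pre-intervention
effects concentrate; the permutation null re-runs the full nested LOOCV on
label-permuted copies.

## Problem sizes and numerical choices

Default runs use the full study geometry (28 regions, 64 sensors, 29 x 4 s
epochs, 22 subjects per cohort). The test suite runs the complete chain at
these sizes once (shared session fixture) and uses smaller systems (2-7
regions) for estimator and oracle checks; the pipeline/CLI round-trip test
uses a reduced cohort (4 subjects, 24 s, 2 bands) purely as an integration
exercise. Tolerances: PDC column normalization 1e-8 (achieved ~1e-15);
PDC against the independent direct-formula oracle 1e-10; graph metrics
against brute-force oracles 1e-10; unit-gain beamformer constraint 1e-8.
Ties in BIC order selection break toward the smaller order; ReliefF ties
break by feature index; OMST restores a directed edge only where the
directed weight is positive. Degenerate inputs (constant samples,
zero-variance feature columns, zero-outflow region pairs) are flagged and
handled explicitly rather than propagated as NaN.

## Known limitations

* The generator's feed-forward coupling topology excludes reciprocal and
  cyclic interactions; real cortical networks have both.
* Band tags of low-frequency (delta/theta) edges are nominal: with
  constant-Q poles the delta resonance is broad, and such an edge's PDC
  leaks into neighbouring bands.
* The laterality index and graph metrics are computed on OMST-masked
  weighted matrices; other masking/weighting conventions exist and are
  only partially exposed as configuration.
* The printed clinical table reproduces published group statistics
  (means, SDs, change, Cohen's d) exactly, but some derived statistics in
  the source publication are internally inconsistent with its own table;
  this package always reports the values recomputed from the table.
* The mixed ANOVA assumes complete cases and exactly two time points.
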