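# Methods

This note records the models implemented in `rmtbi`, the assumptions they
make, the defaults and why, and what the synthetic studies do and do not
establish about real data.

## Scope and data model

All analyses start *after* spatial preprocessing: inputs are assumed
atlas-aligned (a shared 3D integer label map segments every volume), so no
registration, skull-stripping, slice-timing or motion correction of raw
scanner data is performed.  Voxel coordinates are 0-based array indices;
NIfTI affines are carried only as voxel sizes.  Motion screening of DWI
volumes is represented as a user-supplied per-volume exclusion mask rather
than automated artifact detection.

Atlas sizes in the rodent literature vary (116 bisymmetric permeability
regions, 166–173 functional nodes); the node count is therefore a
parameter everywhere.  The default for the bookkeeping identities is
N = 171, the unique value consistent with both the canonical 14,535 node
pairs (N(N−1)/2) and density = average degree / (N−1).

## B1 intensity correction

The coil-sensitivity correction along the slice axis assumes a purely
multiplicative gain measured by a homogeneous phantom: each z-slice is
divided by `profile[z] / mean(profile)`.  A flat profile is the identity,
the whole-image scale is preserved, and a known multiplicative gain is
inverted exactly.  No smoothness model is imposed on the profile.

## Quantitative CBV and permeability screening

`qCBV = (I′_M − I_M)/(I′_B − I_B)` is computed from regional mean
intensities (the median is retained as a QC column; mean − median flags
skewed regions).  Blood intensities come from a designated blood-pool
atlas label averaged per scan.  Permeability is the OLS slope of regional
qCBV over post-contrast scan time, tested one-tailed (H₁: slope > 0)
against the t distribution with n − 2 df — appropriate because the scan
count is small (default 5) and the drift model is linear by construction.
Decisions within a subject use the adaptive two-stage
Benjamini–Krieger–Yekutieli procedure: BH at q′ = q/(1+q) estimates the
null count m̂₀ = m − r₁, then BH again at q′·m/m̂₀; a region is called only
if it also has raw p < 0.05, implementing both printed constraints without
guessing precedence.  Group-level comparisons use pooled-variance
two-sample t-tests per region with the same BKY + raw-p rule across
regions.

Degenerate cases: a perfectly constant timecourse is the exact null
(slope 0, p = 0.5); an exact positive line gives p → 0; zero variance in
both groups of a group test yields p = 1 with a warning.

## Diffusion tensor fit and scalars

The tensor is fit by ordinary least squares on log signals with the
7-parameter design [1, −b gx², −b gy², −b gz², −2b gxgy, −2b gxgz,
−2b gygz] — the simplest deterministic estimator, adequate at the
generator's SNR (S₀/σ = 50); weighted or nonlinear fits are out of scope.
Voxels with any non-positive retained signal are flagged and excluded from
maps (NaN) instead of aborting.  ADC is mean diffusivity; FA uses
eigenvalues clamped at zero (negative eigenvalues, a finite-noise
artifact, are flagged in a QC mask).  FA of an all-zero tensor is defined
as 0.  The package ships a fixed antipodally-symmetric minimum-energy set
of ten unit directions (minimum axis separation 0.75).

Regional statistics treat brain-*area* means as observations, averaged
across subjects within each experimental group first — the granularity of
regional dot plots, where each dot is one area.  This trades subject-level
degrees of freedom for robustness to area heterogeneity; it matches how
such data are displayed and compared.  The Kruskal–Wallis test gates at
0.05; the post hoc is the exact two-sided Mann–Whitney/Wilcoxon rank-sum.

## Functional connectivity

Nuisance regression (intercept + 6 motion + outlier spikes + WM + CSF) is
ordinary least squares; filtering is a 4th-order Butterworth band-pass
(0.01–0.1 Hz) applied forward–backward for zero phase.  Measured gains:
≥ 0.95 at 0.05 Hz, ≤ 0.05 at 0.2 Hz.  Pearson r is clipped to
±(1 − 10⁻⁷) before the Fisher transform so Z stays finite; constant
signals get their rows zeroed with a warning.

Group edge maps convert the per-edge one-sample t (subject Z values vs 0)
to a standard-normal deviate through the t CDF, computed tail-stably as
sign(t)·Φ⁻¹(sf(|t|)).  Zero-variance edges (detected with a relative
tolerance of 10⁻¹⁰ on the mean) receive a ±40 sentinel and a flag.  The
|Z| ≥ 2.3 binarization keeps ties.  Global metrics are computed on the
binary graph — the only reading consistent with printed average degrees
far below N − 1 — with weighted degree (Σ|Z|) retained as a secondary
column.  Average path length is the mean BFS shortest-path length over
connected ordered pairs; disconnected pairs are excluded and counted, and
an empty graph reports no path length.

Node clustering builds a k-nearest-neighbour graph (k = 3 default) on the
distance 1 − |Z|/max|Z| and takes connected components as modules;
deterministic with ties broken by node order.  The construction details of
k-NN clustering on such matrices are not standardised; this variant is the
package's own and is labelled as such.

Degree comparisons are paired over shared nodes: Shapiro–Wilk on the
paired differences gates (p > 0.05) between a paired t-test and the
Wilcoxon signed-rank test.  All-zero differences are the exact null
(p = 1); constant non-zero differences — where the paired t is undefined —
fall back to the exact signed-rank distribution, whose two-sided floor at
n = 5 is 2/2⁵ = 0.0625.

## Behaviour

Open-field zone membership uses sample-and-hold (each sample's zone holds
for the following inter-sample interval), the tracker-software convention;
center + periphery time equals track duration exactly.  The central-zone
area fraction is computed from the actual arena geometry (e.g. 44²/60² =
0.538 for a 60 cm square with the standard 8 cm border) rather than
assuming a nominal percentage, since the fraction depends on arena size.
Arena dimensions are required inputs.  The NOR investigation ratio
IR = novel/(novel + familiar) is compared to chance 0.5 with a
single-sample two-tailed t-test per group; subjects with zero contact are
excluded with a warning.

## Protocol calculators

Pure closed forms: KE = ½mv²; blood volume as 7% of body weight at
1 g/mL (the 1 g ≈ 1 mL blood-density approximation is implied by dosing
by weight); Fe mmol/L = (µg/mL)/55.845; voxel = FOV/matrix.  Display
rounding is 3 significant figures.

## The synthetic studies

Defaults are the study conditions: 6 sham / 8 impacted subjects, 200
BOLD volumes at TR = 1 s, five post-contrast scans over 30 min (scan
count/timing is a free parameter; 5 × 450 s is the default), single-shell
b = 1000 DWI with 1 b0 + 10 directions.  One global seed spawns
per-modality substreams, so a study is internally consistent and each
modality independently reproducible; identical seed + config is
bit-identical.

* **BOLD**: region group = module; region signal √c·F_m + √(1−c)·ε with
  unit-normal factor and noise, so within-module pairwise correlation is
  √(c_i c_j).  Per region, c ~ N(0.6, 0.15) clipped to [0, 0.95] —
  strong within-network coupling typical of region-averaged BOLD, with
  realistic between-animal spread (the spread matters: group-level edge
  t-tests would otherwise saturate any attenuation).  Impacted subjects
  multiply c by 0.5 in cerebrum, hippocampus, cerebellum and thalamus.
  Known nuisance structure (random-walk motion, spikes, WM/CSF, linear
  drift) is mixed in with recorded coefficients.  Region-level signals
  are the primary output; voxel volumes are rendered on demand with
  i.i.d. voxel noise (SD 0.3).
* **QUTE-CE**: tissue intensity I′(t) = I + (CBV₀ + βt)·ΔI_B + noise,
  with CBV₀ = 0.03, blood step ΔI_B = 2000 (arbitrary units, 1000 → 3000),
  voxel noise 0.002 in qCBV units.  The leak template plants
  β = 3 × 10⁻⁵/s in 12 regions of 4/8 impacted subjects and 2 regions of
  2/6 shams.  Configurations where CBV₀ + β·t_max ≥ 1 are rejected as
  unphysical.
* **DWI**: axially symmetric tensors parametrised by (MD, FA) via
  ρ = FA/√(3 − 2FA²), λ₁ = MD(1+2ρ), λ₂ = λ₃ = MD(1−ρ), randomly rotated
  per region (rotations shared across subjects so group contrasts are
  pure MD/FA effects).  Impacted shifts: basal ganglia MD ×0.90 /
  FA ×1.15, thalamus MD ×0.92, cerebellum FA ×0.90.  Gaussian noise
  (SD 20 on S₀ = 1000) is the default because its oracle math is simple;
  Rician is available by flag.
* **Behaviour**: reflected random-walk tracks with a mild center drift;
  NOR contact times split by IR ~ N(0.65, 0.08), identical in both groups
  (the null group-difference scenario with above-chance recognition).

What passing recovery tests shows: the estimators are unbiased and the
decision procedures calibrated *under the generator's assumptions* —
linear leak drift, Gaussian noise, stationary modular covariance, exact
atlas alignment.  What they do not show: robustness to registration
error, physiological noise spectra, partial-volume effects, susceptibility
distortion, or non-linear contrast kinetics.  Realistic MR physics and
anatomically realistic atlases are explicit non-goals.

## Problem sizes

Unit tests run on reduced phantoms (12³–24³ grids, 8–20 regions).  The
recovery analyses use: 20 template studies for the permeability screen
(sensitivity ≥ 0.9, ≤ 1 false region/subject observed ≈ 0.2), 500
replicates for FDR calibration (observed ≈ 0.09 at q = 0.1), 100
replicate studies for the connectivity attenuation property (impacted
degree lower in ≈ 98%), and 100 random graphs (N ≤ 30) against the
Floyd–Warshall oracle.  These sizes give stable Monte-Carlo estimates
while keeping the full suite under a minute of compute for most files.

## Known limitations

* The log-linear tensor fit is biased at low SNR (noisy FA inflates in
  small regions); the regional tests compare groups under equal bias.
* The permeability screen assumes a common region set per subject;
  subjects missing regions are skipped, not imputed.
* The k-NN module clustering has no stability guarantee for weak
  block structure; it is a descriptive device, not an inferential one.
* Group Z maps treat subjects as exchangeable; no covariates.
* The pipeline stage runner analyses in-memory synthetic studies; it
  does not yet ingest external multi-subject datasets end to end
  (the library functions do, per modality).
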