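# Methods

## Scope and data model

The package analyzes paired (pre/post single-dose treatment) breast-MRI
exams alongside two immune readouts — stromal TIL deciles and expression
signature scores — and quantifies their associations. Inputs are assumed
motion-registered, with hand-drawn tumor ROI masks on the same grid as
their series; no registration or segmentation is performed. Coordinates are
0-based (z, y, x); masks must match their series exactly (no resampling).

Units are normalized at the boundary: ADC is stored in mm²/s and displayed
as ×10⁻³ mm²/s, PE and WF display as percent, FTV in cm³. All Δ quantities
are post − pre, uniformly. (TIL change is sometimes written pre − post in
clinical reports even when "response" means an increase; this package uses
post − pre everywhere so a positive Δ always means an increase.)

## DCE kinetics

PE = (S1 − S0)/S0 × 100 and SER = (S1 − S0)/(S2 − S0) per ROI voxel. SER is
computed only where PE ≥ 50%; FTV = (count of PE ≥ 50% voxels) × voxel
volume; WF = count(PE ≥ 50% ∧ SER ≥ 1.1) / count(all ROI voxels) — the
denominator deliberately includes non-enhancing tumor voxels. Both
thresholds (50%, 1.1) are parameters.

Degenerate voxels: S0 ≤ ε or |S2 − S0| ≤ ε, with ε = 10⁻⁶ × the ROI-median
S0, are excluded from the affected map (an undefined SER does not remove a
voxel from FTV); exclusion counts are logged. The delayed phase is treated
as a single S2 volume with no timing correction over its acquisition
window.

Hotspot ("peak") PE and SER are the highest means over 3×3×3 windows whose
center voxel is in the ROI, which lie fully inside the image bounds, and
which cover ≥ 14/27 valid voxels — the window mean is taken over valid
voxels only, keeping peaks lesion-anchored at boundaries. Ties break to the
lowest (z, y, x) center, making the search deterministic. PE and SER peaks
are searched independently. Whether clinical implementations constrain the
window to the ROI interior varies; the minimum-valid-voxel rule is a
parameter.

## ADC

Per voxel, ordinary least squares of ln S(b) on b over all b-values
(default 0, 100, 800 s/mm²); ADC = −slope. A perfusion-suppressed two-point
fit can be requested by passing a b-value subset. Voxels with any
nonpositive signal are excluded rather than clipped (logged); an optional
per-voxel R² diagnostic is available. ROI summaries are arithmetic means
over fitted voxels. Plain unweighted OLS is used; no weighting by signal
level.

## TIL deciles and response

Reads are integer deciles 0–9 (bin k = 10k to 10k+9 percent stromal area).
The two pathologists' reads are averaged (half-integers preserved); reads
≥ 2 deciles apart are flagged as discordant in the log, reflecting the
known inter-reader variability of TIL scoring. A responder shows
Δ(combined decile) > 1; an increase of exactly one decile is a
non-responder. Patients missing a timepoint are non-evaluable and are
dropped from response-stratified analyses with a log entry (association
grids use pairwise deletion instead, with per-cell n reported).

## Expression normalization, scores, tests

Each gene value is divided by the per-sample geometric mean of the
housekeeping genes and log2-transformed. Zeros among non-housekeeping genes
receive a pseudocount of half the smallest positive value in the matrix
(logged); a nonpositive housekeeper is an error naming the gene and sample.
Signature scores are means of member-gene normalized values plus an
optional per-signature range-alignment constant (shipped as editable JSON;
defaults zero). The bundled gene sets are deliberately toy sets — T cell,
NK cell, B cell, dendritic cell, cytotoxic, CD45, eight placeholder genes
each — because commercial panel contents are proprietary; any JSON mapping
set names to gene lists works.

Group testing fits score = μ + group + ε with a single binary fixed effect,
which for two groups is exactly the pooled-variance t-test, and that is how
it is computed. This is a plain linear model, not an empirical-Bayes
moderated test: with signature-level (not gene-level) scores and at least a
few samples per group, the moderation of the variance estimate matters
little, but p-values near the boundary can differ slightly from
moderated-t pipelines. P-values are adjusted across signatures with
Benjamini–Yekutieli FDR (valid under arbitrary dependence; conservative —
null rejection runs well under the nominal 5%). A signature with zero
variance in both groups and equal means is reported t = 0, p = 1 (logged).

Clustering: samples are clustered on per-signature z-scored scores with
Euclidean distance and average linkage, then cut into two groups; the
higher-mean group is labeled immune-activated. Distance, linkage and the
z-scoring are conventional choices made for robustness and determinism and
are configurable. A constant score matrix is an error. "Pre/post samples
cluster together" is measured as dendrogram leaf adjacency of a patient's
two samples — the property a heatmap displays — via
`pair_cocluster_fraction`.

## Association statistics

Spearman correlations use midranks for ties with the asymptotic
t-approximation for two-sided p-values (the cohort sizes this package
targets, n ≈ 13–14, are what that approximation is routinely used for); an
exact-permutation mode is available for n ≤ 8. No multiplicity correction
is applied across the correlation grid — each cell reports ρ, p and its
pairwise-complete n, so sparsely populated cells are visible rather than
silently absorbed. Zero-variance inputs return NaN with a log entry.
Paired t-tests flag zero-variance differences as degenerate rather than
reporting an infinite statistic.

Dichotomies: under fixed thresholds, "diminished ΔPE" means a PE decrease
of 10 percentage points or more (ΔPE ≤ −10), and "high ADC" means strictly
above 0.92×10⁻³ mm²/s — a value exactly at the ADC cut is low. Under the
cohort-median strategy the cuts are the observed medians and values exactly
at a cut go to the non-extreme class (persistent/high) with a log entry;
the threshold actually used is always recorded in the result.

## Synthetic phantoms

Ellipsoidal tumors in a flat background; true PE, SER and ADC vary linearly
(mean + gradient) inside the tumor. Signals are built by inverting the
estimator definitions — S1 = S0(1 + PE/100), S2 = S0 + (S1 − S0)/SER,
S(b) = S0·e^(−b·ADC) — so noiseless round trips are exact to floating
point; ground-truth lesion summaries (FTV, WF, peaks, mean ADC) are
computed by a separate loop-based exhaustive implementation. Background
voxels carry flat S0 with no enhancement and a free-water-like ADC of
2.0×10⁻³ mm²/s; the ROI is the exact ellipsoid (segmentation is not
simulated). Noise is Rician on magnitudes (the physically appropriate MRI
model) or Gaussian for analytic checks, fully seeded. Not simulated:
motion, coil inhomogeneity, fat suppression, partial-volume effects, or
pharmacokinetic (Tofts-type) curve shapes — phantom validation therefore
speaks to estimator correctness, not to acquisition artifacts.

At SNR 20 (b = 0) the Rician magnitude bias inflates the low-signal b = 800
measurements slightly; the resulting ROI-mean ADC bias is ~1% and stays
within the 2% recovery band asserted by the acceptance suite.

## Synthetic cohort

A Gaussian copula draws per-patient latents for each feature (pre and Δ of
FTV, WF, peak SER, peak PE, mean ADC) jointly with TIL latents (pre level
and change). Targeted Spearman correlations are mapped to latent Pearson
correlations by r = 2 sin(πρ/6); every downstream marginal transform is
monotone, which preserves Spearman. Default targets are ΔPE −0.69 and
pre-ADC −0.67 vs ΔTIL (negative), pre-WF +0.51 and pre-PE +0.48
(positive).

Those four targets with all other off-diagonals zero are mutually
infeasible (the TIL-change column's squared loadings sum to 1.42), so
feature–feature correlations among variables loading on the same TIL
quantity are completed with a one-factor model, corr(Fᵢ, Fⱼ) = rᵢ·rⱼ —
positive semi-definite by construction, with biologically plausible implied
cross-correlations (e.g. ΔPE and pre-ADC positively correlated through the
shared immune-response factor). Explicit targets always override the
completion, and the final matrix is eigenvalue-checked; infeasible requests
are rejected with a diagnostic.

Because decile binning, boundary clipping and dual-read noise all shrink
the Spearman correlation an observed TIL quantity can carry, the generator
measures that attenuation once on a large fixed internal sample and
inflates the latent correlation by 1/λ before the sin transform; a target
unreachable after attenuation is rejected. Recovery at n = 2000 is within
±0.05 of each target.

TIL marginals: true pre-treatment deciles uniform on 2–7 and true changes
in {−2…+1} (non-responders) or {+2, +3} (responders), a monotone quantile
map of the change latent calibrated so the responder fraction matches the
request (default 6/13). These ranges keep 0–9 boundary clipping rare.
Pathologist reads are the true decile plus rounded Gaussian noise (SD 0.5
deciles by default, configurable; reads clipped to 0–9). Feature marginals
are Gaussian with means/SDs at typical HER2+ lesion magnitudes (e.g. peak
PE ~ N(200, 40)%, pre-ADC ~ N(0.92, 0.15)×10⁻³ mm²/s, ΔPE ~ N(−10, 25)%)
and are fully configurable — cohort-level distributional parameters are not
something a 14-patient pilot pins down, so they are conditions of the
simulation, not estimates. WF/FTV/ADC values are clipped to their physical
ranges (tail events only).

Expression model, per non-housekeeping gene g, patient p, sample s (log2):
baseline μ_g ~ N(8, 1), plus a per-sample library factor N(0, 0.3) on all
genes (removed by normalization), plus activation_effect (default 2.0) for
signature genes in immune-activated patients, plus a patient profile
u_{p,g} ~ N(0, patient_sd²) shared by the patient's two samples, plus a
treatment shift t_{p,g} ~ N(0, treatment_sd²) applied to the post sample
only, plus residual per-sample noise N(0, noise_sd²). Housekeepers carry
only baseline N(10, 0.5), the library factor and small (0.05) noise — no
group effect, keeping normalization honest. Defaults: patient_sd 1.0,
treatment_sd 0.25, noise_sd 0.5 — a microenvironment whose baseline state
dominates its treatment response, consistent with pre/post samples of one
patient clustering together. Activation labels default to the ground-truth
responder designation (near-concordance of TIL response and expression
cluster is the observed regime); `activation_flip_prob` decouples them.

What the generator does not emulate: count overdispersion and
mean–variance coupling of real panels, correlated genes within a signature
beyond the planted group shift, batch effects, QC failures, or any spatial
tissue structure. Passing tests on this cohort demonstrate that the
analysis chain recovers structure it is pointed at under controlled noise —
not that real cohorts of n ≈ 14 would yield stable correlation estimates
(they would not; at n = 13 the sampling SD of ρ ≈ 0.2).

## Validation strategy and problem sizes

The test suite validates in four layers: exact identities (noiseless
phantom round trips, closed-form examples), brute-force oracle equivalence
(FTV, WF, hotspot searches, Spearman with ties, geometric-mean
normalization, BY adjustment — each against independent loop
implementations on ≥ 100 random instances), stochastic parameter recovery
(ADC within 2% over 50 Rician phantoms at SNR 20; copula targets within
±0.05 at n = 2000), and null calibration (BY rejection ≤ 5%, Spearman
t-approximation ≈ 5% at n = 13, 1000 replicates each). Structure-recovery
simulations use 40 cohorts of 20 patients (label recovery at effect/noise
= 4) and 20 cohorts of 14 patients (co-clustering at a 4× patient/treatment
variance ratio with residual noise 0.25); phantom checks use 64³ grids with
~17k-voxel tumors and 20³ grids for the noise sweeps. These sizes give
stable Monte-Carlo estimates while keeping the full suite in the tens of
seconds.

## Known limitations

- No motion correction, distortion correction, or segmentation: garbage
  registration in, garbage kinetics out.
- The two-group expression test is unmoderated; for gene-level testing at
  panel scale an empirical-Bayes method would be preferable.
- The exact-permutation Spearman mode enumerates all n! permutations and is
  limited to n ≤ 8.
- QC exclusion of expression samples is a config-driven blacklist plus a
  minimum-housekeeper-signal rule, not a reimplementation of any vendor
  pipeline's metrics.
- The cohort generator's independence of latent features given the factor
  structure is an assumption of convenience, not biology.
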