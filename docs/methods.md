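# Methods

`nirsconn` implements a complete resting/listening-state fNIRS
functional-connectivity analysis — raw dual-wavelength intensities to
channelwise networks and longitudinal edge statistics — together with a
synthetic-cohort generator that provides ground truth for every stage. This
note records the models, the parameter choices that matter, and the design
decisions taken where more than one defensible option existed.

## Optical model

A continuous-wave instrument records intensity at two wavelengths
(730 and 850 nm) for each of 48 source–detector channels at 11 Hz. Under the
modified Beer–Lambert law, the change in optical density at wavelength λ is

    ΔOD(λ, t) = [ε_HbO(λ)·ΔC_HbO(t) + ε_HbR(λ)·ΔC_HbR(t)] · L · DPF(λ),

with ε the molar extinction coefficients, L the source–detector separation
(3 cm) and DPF the differential pathlength factor. Extinction coefficients
come from the Gratzer/Prahl compiled hemoglobin spectra:
ε(730) = (450.0, 1102.2) and ε(850) = (1058.0, 691.32) M⁻¹cm⁻¹ for
(HbO, HbR). DPF defaults to 6.0 at both wavelengths (a conventional
adult-head value; configurable). Baseline intensity I₀ defaults to 1.0 in
arbitrary units — only intensity ratios matter under the model. The
generator's forward map (concentrations → intensities) and the preprocessing
inversion (intensities → OD → concentrations) are exact algebraic inverses;
the acceptance suite verifies round-trip recovery to 1e-8 relative error.
Recovered concentrations are *relative* (micromolar times an unresolved
partial-volume factor): Pearson correlations downstream are invariant to
per-channel scale, so no absolute calibration is attempted.

## Montage

The built-in `whole_head_48` layout defines 48 channels over 24 sources and
16 detectors with fixed 1-based numbering, lobe bands (occipital 1–8,
temporal 9–16, parietal 17–28, frontal 29–48) and named-area labels on the
channels used in edge-level reporting (V2 on 4, V1 on 7, supramarginal
gyrus/Wernicke's area on 10, DLPFC on 34/45/46, Broca's pars opercularis on
44, pars triangularis on 47/48). Optode coordinates are illustrative: the
layout is a plausible whole-head grid, not a digitised registration.

## Synthetic cohort

The generator emulates a three-group longitudinal design: a treated group
(MT, n = 34), a waiting-list group (WL, n = 32) and healthy controls
(HC, n = 17), each recorded at two time points with GAD-7 (0–21) and PHQ-9
(0–27) symptom scores. Screening rules hold by construction: HC baseline
GAD-7 < 5, anxiety groups ≥ 5 (drawn as 5 + a lognormal excess, since the
group means sit close to the screening floor).

**Connectivity structure.** Each group's channelwise correlation matrix is a
two-factor loading model: r_ij = a_i·a_j + b_i·b_j·[same lobe], with a
global factor (between-lobe connectivity) and per-lobe factors (within-lobe
connectivity). The model is positive definite by construction because every
channel retains idiosyncratic variance 1 − a² − b² (floored at 0.015).
Loadings are calibrated by a probe-sample iteration so that the *subject-
level expectation* of the global mean correlation and of the within-lobe
mean hit the group targets — by default 0.437/0.448/0.501 (global) and
0.754/0.752/0.814 (top-edge level) for MT/WL/HC. Subjects draw one
multiplicative connectivity scale (SD 0.25, clipped at ±2 SD, mean exactly
1) plus per-channel loading jitter (SD 0.04), shared across their two
sessions so pre/post data are genuinely paired; a small per-session loading
wobble (SD 0.02) adds test-retest variability.

**Planted effects.** Three effect edges (10–34, 7–48, 4–47) carry baseline
connectivity overrides (0.601, 0.357, 0.267) and, in the treated group only,
pre-to-post reductions (−0.302, −0.328, −0.347) with per-subject effect SD
0.15. Entry edits are performed as rank-1 "edge factors", which stay
positive definite as long as both endpoint channels hold |Δ| of
idiosyncratic variance in reserve; the calibration reserves that headroom on
effect-edge channels, and the rare occasions where a draw still exhausts it
are clipped and counted as repair events.

**Symptom coupling.** Each treated subject's GAD-7 change is drawn through a
Gaussian rank copula against the subject's realized (sample) connectivity
change on the coupling edge (10–34), with target Spearman ρ = −0.45
(copula Pearson parameter 2·sin(πρ/6)); GAD-7/PHQ-9 changes otherwise follow
group-specific normal distributions (MT −1.97 ± 2.15 and −4.19 ± 3.62; WL
0.72 ± 4.60 and −1.28 ± 2.87) rounded and clipped into instrument bounds.

**Signals and noise.** Hemodynamic series are correlated Gaussian noise
(Cholesky of the subject matrix) shaped into the hemodynamic band by a
zero-phase 0.15 Hz low-pass, at 0.5 µM amplitude; HbR is the typical
anticorrelated mirror (−0.33·HbO plus independent noise). Physiological
noise adds per-channel random-phase sinusoids (cardiac 1.2 Hz at 0.8 µM,
respiratory 0.3 Hz at 0.3 µM, Mayer waves 0.1 Hz at 0.06 µM), a random-walk
drift (0.008 µM/sample) and white noise (0.4 µM); with these defaults well
over half the contaminated variance lies outside the 0.01–0.2 Hz analysis
band, so the band-pass stage is observably doing work. Motion artifacts
(default 0.5 events/minute) are spikes (1–3 samples, ~50 µM ≈ 1 OD unit) and
persistent baseline shifts, with a ground-truth event log. Recording length
defaults to 300 s — sessions in the emulated design run 8–15 min, but 300 s
keeps simulation studies tractable and is configurable.

**What the generator does not emulate.** No photon-transport or layered
tissue model, no task-evoked hemodynamic response, no systemic (shared
superficial) physiology — noise is channel-independent, so the generator
cannot produce the spurious *common-mode* connectivity inflation real
short-separation regression targets. Passing tests therefore demonstrate
correctness of the pipeline's computations and calibration of its
statistics, not robustness to every contamination mode of real data. A
documented consequence of the in-band noise floor: measured correlations
are attenuated multiplicatively by roughly 5–10% relative to the planted
values at the 300 s default duration.

## Preprocessing

Stage order: CV quality control → optical density → motion correction →
band-pass → automated borderline inspection → onset/offset truncation →
MBLL inversion. Excluded channels are masked, never dropped; masks propagate
into connectivity matrices as missing rows/columns.

* **CV QC.** CV = 100·SD/mean of raw intensity per wavelength (sample SD),
  aggregated per channel as the worst case over wavelengths. Classes:
  optimal (CV ≤ 5), borderline (5 < CV ≤ 20), excluded (CV > 20); boundary
  values sit with the lower class. A participant is dropped when fewer than
  80% of channels survive.
* **Automated inspection.** Flat-line (relative running SD < 1e-5 for
  > 10 s) and saturation checks apply to *all* channels — a dead optode can
  have a deceptively optimal CV; a residual-drift check (post-filter linear
  trend larger than 3 channel SDs, a robust criterion chosen because the
  band-limited series is too autocorrelated for a naive slope test) applies
  to borderline channels. Any hit excludes the channel.
* **Motion correction.** The statistic is the signal change across a 1 s
  sliding window. A sample is flagged when |change| exceeds 6× a robust
  (MAD) SD of the statistic — interpreting the conventional "std" threshold
  as an SD multiplier — or 0.5 OD absolutely ("amp"). The SD rule is muted
  below a 0.02 OD noise floor: on nearly noise-free channels the extreme
  excursions of ordinary band-limited fluctuations reach ~6 robust SDs and
  would otherwise be false alarms. Whether these thresholds should act on
  OD or raw intensity is ambiguous in closed implementations; OD is used
  here. Corrections first realign the post-segment tail (a baseline shift
  leaves a level offset that interpolation alone would bridge but not
  remove, and whose step response would leak through the high-pass for
  minutes), then replace the flagged segment (±1 s margin) with a cubic
  spline anchored on clean neighbours. A channel flagged over more than
  half its length is masked instead.
* **Band-pass 0.01–0.2 Hz.** Zero-phase Butterworth, realised as a cascade:
  4th-order low-pass at 0.2 Hz, linear detrend, then subtraction of a
  4th-order 0.01 Hz low-pass baseline. A direct digital band-pass at these
  corners (0.0018 of Nyquist) is numerically fragile: the forward-backward
  pass leaves boundary transients of the ~40 s poles that dominate the
  stopband. Order 4 (not 3) keeps the two-pass passband deviation within
  1 dB over 0.02–0.15 Hz, since filtfilt squares the single-pass response.
  Contract, verified by sinusoid probes: ≤ 1 dB deviation in 0.02–0.15 Hz,
  ≥ 20 dB attenuation at 1.0 Hz and 0.001 Hz, zero phase lag.
* **Truncation.** 10 s per end by default (configurable up to 30 s).
* **MBLL.** Per channel and time point a 2×2 linear solve; baseline I₀ is
  the temporal mean of each channel's intensity (first sample and median are
  alternatives).

## Connectivity and networks

Functional connectivity is the Pearson correlation of the preprocessed HbO
series (HbR is not used), giving a 48×48 matrix per participant/session with
a Fisher-z twin (atanh, clamping |r| ≥ 1 to 1 − 1e-7 with a warning).
Zero-variance channels are masked with a relative tolerance (rounding-level
variance on a constant channel would otherwise produce garbage
correlations). The global mean FC averages the unique valid off-diagonal
entries in r units. Sparsity thresholding retains the top floor(s·E_valid)
edges ranked by *signed* r — reported negative post-treatment values are
weak edges, not strong ones; magnitude ranking is available behind a flag —
with lexicographic tie-breaks; at s = 0.3 on a fully valid matrix this is
exactly 338 of 1128 edges (0.31 appears once in the source material's
description of the same analysis; 0.3 is used throughout). Group matrices
are pairwise-complete elementwise means.

## Statistics

* **Edgewise longitudinal tests** run per retained edge on Fisher-z values
  (variance-stabilised) across paired subjects; summaries are reported in r
  units. Default branch is the paired t (Wilcoxon available); edges with
  fewer than 3 complete pairs are flagged untestable. The edge universe is
  the treated group's baseline-network edge set (338 edges at default
  sparsity); all-1128 is a configuration alternative. Benjamini–Hochberg
  FDR at q < 0.05 is applied within each analysis family separately.
* **Wilcoxon signed-rank**: zeros dropped, midranks for ties, exact sign-flip
  null for n ≤ 25 without ties, otherwise normal approximation with
  continuity and tie corrections.
* **Normality gate**: Shapiro–Wilk on paired differences at α = 0.05 selects
  paired t vs Wilcoxon for the global-FC change; overridable.
* **Group baseline comparison**: tie-corrected Kruskal–Wallis H on
  per-subject global FC, with Dunn's pooled-rank z post hocs under a
  Bonferroni k(k−1)/2 multiplier (implemented in-package; the BH routine is
  likewise in-package with the standard step-up definition, and both are
  cross-checked against independent implementations in the tests).
* **Symptom scales**: within-group paired t on change scores (df = n − 1);
  between-group baselines by independent t (anxiety groups) and
  Kruskal–Wallis (all three).
* **Δ–Δ correlation**: Spearman rho with midranks between per-subject GAD-7
  change and per-edge FC change, exact permutation p for n ≤ 9, t
  approximation otherwise; computed on the edges surviving FDR.

Two-sided tests throughout.

## Problem sizes used in validation

The Monte-Carlo validation studies run at the design size — 34 paired
subjects, 338 edges — with 200 replicates for null FDR control and 100 for
planted-effect recovery, on 300 s fast-path cohorts (the optics round trip
is exact, so skipping it in replicate loops is statistically neutral; the
full optics chain is exercised in the headline cohort run and in the test
suite). The null FDR check reports the empirical mean false-discovery
proportion with a binomial 95% CI; under a global null this equals the
fraction of replicates with any discovery, and BH guarantees it ≤ q.

## Known limitations

* Channel-independent noise only (see above); no systemic physiology.
* The motion-correction algorithm is a reasonable reconstruction of a
  closed-source tool's "(std, amp)" thresholds, not a reimplementation of a
  published algorithm.
* Group-level network topology beyond edge retention and mean retained
  weight (clustering, efficiency, small-world indices) is out of scope.
* The generator's scale-score distributions are moment-matched normals /
  lognormals, not item-level simulations of the instruments.
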