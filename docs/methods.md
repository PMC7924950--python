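# Methods

This note documents the models, algorithms and numerical choices behind
`slowwave`, and what the synthetic-data generator does and does not
emulate.

## The recording model

The package analyzes intracellular membrane-potential (Vm) and local
field potential (LFP) recordings acquired under slow-wave-oscillation
(SWO) conditions (anesthesia, slow-wave sleep): the network alternates
at roughly 0.7 Hz between a hyperpolarized, quiescent *Down* state and
a depolarized, synaptically bombarded *Up* state. Every stage of the
pipeline is built around this two-state picture.

## Up/Down state segmentation (`slowwave.states`)

The detector smooths the trace with a 200 ms centered moving average
(shrinking windows at the edges), thresholds at the mean plus 0.5
standard deviations of the smoothed trace, merges Up fragments
separated by less than 250 ms, and discards Up states shorter than
200 ms. Down states are the complement. Because the threshold is
referenced to the trace's own mean and SD, detection is invariant to
constant voltage offsets.

State boundaries use the half-open convention [onset, offset), with the
onset at the first supra-threshold sample of the merged run. For a
two-state trace with Up fraction *d*, the threshold sits at fraction
`q = d + 0.5 * sqrt(d (1 - d))` of the transition edge; at *d* ≈ 0.28
(the generator's default duty cycle) *q* ≈ 0.5, so detected onsets are
unbiased estimates of the mid-ramp boundary.

Cross-channel pairing uses the 500 ms rule: candidate onset pairs with
|lag| < 500 ms are accepted greedily, smallest |lag| first, each onset
used once. Propagation probability is the fraction of reference-channel
onsets followed (0 < lag ≤ 500 ms) by a paired onset; directional
probability is the fraction of non-tied pairs in which channel A leads,
with conditional mean |lag| per direction.

## Up-state featurization (`slowwave.features`)

Thirteen features per Up state (means, SD, extrema, amplitude,
derivative extrema, transition slopes, slope ratio, peak count,
peak-to-peak, duration); see the module docstring for the full table.
Key conventions:

* **f5 (amplitude)** is the Up mean minus the mean of the two flanking
  Down states (robust to slow drift); states without both flanking
  Downs fall back to the global Down mean and are flagged. Because the
  detected interval contains the outer half of each transition ramp,
  the measured f5 is slightly below the plateau-to-floor amplitude —
  the closed-form dilution is `amp/4 * (r_up/2 + r_dn/2) * (1/dur_up +
  1/dur_down)` for ramp durations `r` — and the generator records this
  convention-consistent expectation (`f5_expected_mv`) as its truth.
* **f11 (peak count)** counts local maxima of the 200 ms-smoothed
  segment at least 0.3 segment-SDs above the segment mean and 160 ms
  apart (the higher of two close candidates survives). The SD
  reference is the smoothed segment itself, a per-state normalization.
* **f8/f9 (transition slopes)**: a −100..+200 ms window around the
  transition is smoothed (100 ms), its absolute derivative thresholded
  at mean + 0.3 SD to delimit the transition, and a least-squares line
  is fitted to the **raw** voltage over the delimited region (fitting
  the smoothed voltage would underestimate a 100 ms ramp by ~20%).
  The method is accurate to <5% while the ramp is at least as long as
  the smoothing window (≈ 80–250 mV/s at 25 mV amplitude) and
  increasingly underestimates faster transitions (−7% at 300 mV/s,
  −21% at 400 mV/s); slope features should be interpreted accordingly.
* **f6/f7** are central differences at the native rate on the despiked
  trace; in noisy recordings they are noise-extreme statistics and are
  retained for completeness rather than discriminative power.

Spike removal subtracts the intrinsic mode functions whose median
Hilbert instantaneous frequency exceeds 50 Hz.

Passive properties: input resistance is the regression slope of
steady-state voltage deflection on injected current (mV/pA → MΩ), the
membrane time constant is the (interpolated) time to 63.2% of the
steady-state increment, the capacitance is τ/R. Evoked-response onset
is the first post-trigger crossing of baseline mean + 2 baseline SDs
sustained for 10 ms; the amplitude is the average's peak over baseline
and the slope a line fit from onset to peak. The 2 SD/10 ms onset
criterion is this package's own definition.

## EMD, MEMD and NA-MEMD (`slowwave.emd`)

Classic EMD sifts with cubic-spline envelopes through the extrema
(two extrema mirrored across each trace end) and the Rilling
three-threshold stopping rule (θ₁ = 0.05, θ₂ = 0.5, α = 0.05, at most
10 sifts per mode). The decomposition is exactly complete by
construction: each IMF is a difference of successive residuals, so the
telescoping sum reproduces the input to float rounding (the
reconstruction tests require < 1e−9 relative error and observe
~1e−16).

Multivariate EMD projects the channel vector onto a deterministic
low-discrepancy direction set (Hammersley points pushed through the
normal quantile and normalized; uniform angles in two dimensions; 64
directions by default). For each direction, all channels are
interpolated at the extrema of the directional projection; max- and
min-envelopes are averaged per direction and across directions. With a
direction set closed under sign flip this equals the maxima-only
estimator of the standard multivariate formulation at half the
projections. All channels share one mode axis, so every channel yields
the same number of IMFs.

NA-MEMD appends white-Gaussian-noise channels (one by default, SD
matched to the mean channel SD, seed-reproducible), runs MEMD, and
discards the noise channels. On broadband input the decomposition
behaves as a quasi-dyadic filterbank: successive IMF median frequencies
halve (measured mean ratio ≈ 0.55 on white noise).

Median instantaneous frequency per IMF is amplitude-weighted over the
interior 90% of samples (low-amplitude stretches carry meaningless
phase slips). The SWO mode is the IMF with maximum |Pearson r| against
the membrane voltage. SWO phase convention: 0° at the depolarized peak,
±180° at the trough; Up onsets fall at negative phases.

## Band energy and circular statistics (`slowwave.spectral`)

Bands: theta 6–10, beta 10–20, gamma 20–80 Hz. IMFs are assigned to a
band by median instantaneous frequency; the band signal is their sum,
its energy the squared Hilbert amplitude (mean energy per phase bin,
not integrated energy). Profiles average energy in 36 10° SWO-phase
bins over Up-state samples only, excluding the outer 5% of the trace
(spline envelopes are unconstrained beyond the outermost extrema, so
IMF energy is unreliable at the edges), and are normalized to their maximum
(the raw peak energy is kept for classification features: two features
× three bands per cell). The profile peak is the maximum bin; a
three-point parabolic interpolation (`refined_peak_phase_deg`) removes
the 10° quantization when a scalar phase estimate is needed.

The Rayleigh uniformity test uses z = nR̄² with the standard finite-n
corrected p approximation (type-I error measured 0.046–0.054 at
α = 0.05, n = 100). SWO cross-correlation between channels is reported
at zero lag; the full lag function is computed internally and its peak
lag logged.

## Synaptic-event detection (`slowwave.events`)

The derivative is computed with a Parks–McClellan equiripple low-pass
differentiator (order 20, cutoff 200 Hz), group-delay compensated
(type III, integer delay) and gain-calibrated against the ideal jω
response over the low passband. Note the physics of a 21-tap design:
at a 20 kHz rate the transition band is necessarily wide (a 400 Hz tone
retains ~85% of the passband-relative gain) and broadband white noise
leaks through the stopband ripple; at a 2 kHz rate the same design
attenuates 400 Hz by ~99%. Detection itself is scale-free (threshold
at mean ± 2 SD of the derivative), one event per contiguous
supra-threshold run, timestamped at the extremal derivative.

The depolarizing/hyperpolarizing (DH) ratio profile counts events of
each polarity per SWO-phase bin, normalizes each polarity to its own
maximum bin (per cell), and subtracts hyperpolarizing from
depolarizing; values lie in [−1, 1].

A 2 SD threshold presumes that the trace between events is smooth: if
white noise dominated the derivative, threshold crossings would occur
at a fixed rate for any detector. The event fixture therefore uses a
pure-tone slow-wave background (whose derivative peak is 1.41 SD < 2
SD by construction), a realistic several-Hz event rate (events then
contribute to the derivative SD as real synaptic barrages do) and
small instrument noise — the regime in which the empirical 2 SD rule
is meaningful.

## Classification and boundary analysis (`slowwave.classify`)

Cells are classified with a soft-margin linear SVM (C = 1.0, no kernel
or hyperparameter search) on standardized per-cell mean feature
vectors. Standardization statistics are always fit on training cells
only — in every stratified k-fold split (k = 10 by default;
"cross-validated 10 times" is interpreted as 10-fold) and in
one-animal-out validation, where all cells of one animal are held out
together and folds whose training set collapses to one class are
flagged. RFE removes the feature with the smallest |standardized
weight| one at a time (ties to the lower index); the accuracy curve
re-fits on each top-m subset of the final ranking.

A third group of cells is analyzed geometrically: all cells are
projected onto the unit normal of the separating hyperplane
(z·w/|w| + b/|w|), so the projection's sign reproduces the predicted
label, and projected distributions are compared with the two-sided
rank-sum test. Optogenetic pathway labeling is a helper: a cell is
"indirect" when the median depolarization within 0.8–5 ms of the light
pulse reaches 4 mV, otherwise "putative direct".

## Statistics (`slowwave.stats`)

Two-sided Wilcoxon rank-sum (exact for n ≤ 25 per group without ties,
normal approximation with tie and continuity corrections otherwise),
Wilcoxon signed-rank (zeros dropped; exact sign-flip enumeration for
n ≤ 12, which stays exact under tied |differences|), and step-down
Holm–Bonferroni correction. A batch interface runs a named family of
comparisons and returns raw and adjusted p-values with decisions.

## The synthetic-data generator (`slowwave.synthetic`)

The generator emulates the statistical structure the analyses assume,
not the biophysics. Up/Down alternation is a two-state semi-Markov
process with truncated-Gaussian durations (default Up 0.4 ± 0.05 s at
0.7 Hz, duty ≈ 0.28 — see the threshold-bias argument above);
transitions are piecewise-linear ramps (sigmoidal option) whose state
boundary is the 50% point of the ramp; intra-Up peaks are raised-cosine
bumps (150 ms wide, ≥ 160 ms apart, kept clear of the transition ramps
so the 200 ms smoothing can resolve them); band bursts are
Tukey-enveloped sinusoids centered where the skeleton's Hilbert phase
(the ground-truth SWO phase) crosses a target, with von Mises jitter;
synaptic events are difference-of-exponential deflections (2 ms rise,
15 ms decay) from a phase-modulated Poisson process; spikes are 2 ms
triangular 60 mV transients; noise is additive Gaussian plus a slow
within-Up fluctuation. Default test rate is 1 kHz; 20 kHz mimics
acquisition.

What it does **not** emulate: conductance-based membrane dynamics,
spike waveform diversity, non-stationary anesthesia depth, electrode
drift, or correlated (pink) instrument noise. Passing tests therefore
demonstrate correctness of the analysis chain on data with the assumed
structure, not robustness to every pathology of in vivo recordings.

### Cohort presets

`DLS_LIKE_SPEC` / `DMS_LIKE_SPEC` build a two-region cohort whose
effect directions mirror a lateral/medial striatal contrast: more
intra-Up peaks and slightly longer Up states laterally (2.3 vs 1.4
peaks; 0.65 vs 0.62 s), larger Up amplitude and steeper Up→Down
transition medially (26 vs 20 mV; 170 vs 90 mV/s). Magnitudes are this
package's scaled-down design choices. Per-cell heterogeneity is drawn
per parameter; two structural choices keep the discriminative signal in
the three designed features (peak count, amplitude, fall slope): the
rise slope is a broadly dispersed per-cell multiple of the fall slope
(so neither the rise slope nor the slope ratio carries region
information), and the resting potential varies by 7 mV SD across cells
(matching in vivo spread), which decouples the absolute-voltage
features from the amplitude effect. The standard cohort is 30 cells
per region across 15 animals (≈ 4 cells per animal), assigned
round-robin so animals span regions. Drawn slopes are clamped to keep
every transition ramp under 300 ms so the skeleton remains feasible.

With this design, 10-fold accuracy on the top-3 RFE features is
≈ 99%, and the RFE top 3 equals {peak count, amplitude, fall slope}
in about three quarters of random cohorts.

### Paired traces and protocols

Paired generation shares the Up-state skeleton and shifts trace B's
states by signed lags (positive = A leads, probability `p_a_leads`;
magnitude truncated-normal). RC step responses follow
V(t) = V₀ + IR(1 − e^(−t/RC)) with unit bookkeeping MΩ·pF = µs and
pA·MΩ = µV. Evoked trials are a flat baseline, a linear ramp of given
slope to a given amplitude, then exponential decay.

## Problem sizes

Default test and acceptance problem sizes are chosen for desk-scale
runs: 40–60 s traces at 1 kHz for detection/featurization, 2048-sample
white-noise realizations for the filterbank measurement (20 seeds),
60-cell cohorts over 20 random cohorts for the end-to-end
classification mirror, 300 paired Up states for propagation
statistics, and 1000–2000 simulations for test-calibration checks.
The full suite runs in ~4 minutes on one CPU.

## Known limitations

* Transition-slope estimates saturate for ramps shorter than the
  100 ms smoothing window (see above).
* The 21-tap differentiator cannot realize a sharp 200 Hz cutoff at a
  20 kHz rate; event detection is unaffected (threshold is in SD
  units) but broadband noise should be band-limited before
  differentiation at high rates.
* EMD-based band profiles are contaminated by transition-edge leakage
  when slow-wave edges are much larger than band-limited bursts; the
  band-phase recovery fixture uses sigmoidal transitions for this
  reason, and phase estimates carry a residual bias of ~5–10° on
  trapezoid-like waves.
* LFP Up-state detection applies the same threshold detector to the
  sign-adjusted smoothed SWO IMF of the LFP; the original analysis
  does not specify its LFP onset method, so cross-modality onset
  comparisons should be treated as convention-dependent.
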