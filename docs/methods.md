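# Methods

This note documents the models, numerical choices, and deliberate
simplifications behind `prestim`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Stimulus waveforms

Rhythmic stimulation is a raised cosine, L(t) = (1 − cos 2πft)/2, sampled
at the 240 Hz monitor frame rate over an integer number of cycles. A
signed sine would go negative, which has no luminance interpretation; the
raised cosine starts and ends dark, peaks once per cycle, and has a single
spectral line at f. The final frame is forced dark: the cycle completes
exactly one frame interval after the last sample, and that frame belongs
to the dark gap, so snapping it to zero keeps the start/end-at-zero
contract while shifting the mean by well under 1/(2·n_frames).

The arhythmic control chains complete single raised-cosine cycles with
frequencies drawn uniformly from the integers 13–24 Hz excluding 15, 18
and 20 Hz (harmonics of 5 and 9 Hz). Chaining is greedy: cycles are
appended while the running total stays within the 2 s target, and the
first draw whose cycle would overflow ends the chain (the drawn frequency
is discarded). Among the candidate stopping rules consistent with a
"comparable to 2 s" duration, this one reproduces both the mean (≈1.97 s)
and the spread (SD ≈ 0.02 s) that the acceptance suite checks; a
redraw-until-nothing-fits rule yields a longer mean and roughly half the
spread. Post-stimulation gaps are half a stimulation cycle rounded to
integer milliseconds (100 ms at 5 Hz, 56 ms at 9 Hz) and a fixed 50 ms
for the control; frame-level quantization of the gap is not modelled.

## Synthetic cohort

The EEG model is additive, per trial spanning −3.4…+2.5 s at 500 Hz:

- **1/f^χ background** (χ = 1.0 by default, `noise_exponent`): white noise
  spectrally shaped in the frequency domain, scaled to `noise_std` = 10 µV
  per channel — a typical broadband EEG amplitude.
- **Ongoing alpha**: a 10 Hz sinusoid with per-trial random phase,
  amplitude 4 µV at the posterior maximum, attenuated anteriorly.
- **Entrained component**: at the group's stimulation frequency
  (5 Hz theta, 9 Hz alpha), phase-locked to stimulation onset at −2.1 s,
  lasting until the group's half-cycle gap. The arhythmic control is
  driven by one participant-specific cycle chain (mirroring how each
  control participant saw a unique waveform). Amplitude ramps as
  1 − exp(−t/τ) with τ = `entrain_ramp_tau` = 0.5 s, reflecting that
  entrainment develops over time and plateaus; the plateau amplitude
  `entrain_amplitude` defaults to 6 µV at the occipital peak — the scale
  of a robust steady-state visual response — with a fixed spatial profile
  peaking at O1/O2/Oz (1.0), falling through parieto-occipital (0.7) and
  parietal (0.4) rows to 0.05 frontally and 0 on EOG channels.
- **Evoked transient**: a damped 8 Hz oscillation (decay 0.3 s, 5 µV)
  after stimulus onset, common to all groups.
- **Artifacts** (optional, off by default): single-channel 500 µV step
  discontinuities ("jump"), 35 Hz bursts of ~60 µV across a patch of
  eight adjacent channels ("muscle" — phasic EMG contaminates a region,
  not one electrode), and 200 µV frontal deflections ("blink").

Behaviour follows an equal-variance signal-detection model: participant
d′ is drawn from the group's Normal(M, SD) truncated at zero, with the
printed group parameters as defaults (theta 1.28/0.55, alpha 1.46/0.60,
control 1.18/0.50, no-entrainment 1.27/0.53). Familiarity of old pairs is
Normal(d′, 1), of recombined pairs Normal(0, 1); the response is "old"
above the criterion c = 1.13, chosen so that the implied false-alarm
(~13%) and hit rates (~50–62% across groups) sit where the printed group
rates sit. One percent of trials are "missed responses" (no button press
within 3 s). Reaction times are shifted-lognormal and feed only
descriptive summaries.

What the generator does **not** emulate: volume conduction and realistic
head geometry, the distinction between true phase-entrainment of an
endogenous oscillator and a summed series of evoked responses (treated as
one additive component, since EEG cannot separate them in this paradigm),
non-stationary noise, and electrode drift. Passing tests therefore show
that the *analysis machinery* is correct and calibrated on data with the
assumed structure — not that the biology behaves this way.

## Preprocessing

Band-pass filtering is a 4th-order zero-phase Butterworth (0.5–40 Hz,
forward–backward). Epochs run −3.4…+2.5 s; markers whose window leaves
the recording are flagged (`edge`), never silently dropped.

Artifact rejection computes, per artifact type, a per-channel metric —
jump: absolute derivative of the median-filtered signal (kernel 15
samples; the filter suppresses background high-frequency noise but keeps
steps; samples at the filter edges are discarded as the shrinking window
distorts them coherently across channels); muscle: Hilbert envelope of
the 30–40 Hz band smoothed over 200 ms. The conventional muscle detector
works above ~60 Hz; with data low-passed at 40 Hz the 30–40 Hz envelope
is the closest in-band surrogate. Each metric is z-transformed per
channel against its **median/MAD** over the whole epoch set (a plain
mean/SD normalisation is self-defeating: a large artifact inflates the SD
enough to cap the reachable z below the cutoff), summed over channels and
divided by √n_channels, and a trial is rejected when its maximum over
time exceeds the cutoff (60 for jumps, 30 for muscle). A trial exceeding
both cutoffs is attributed to the type it exceeds by the larger factor.
Scores are computed on the *unfiltered* epochs: a zero-phase 0.5 Hz
high-pass smears a step into a slow bump, so jumps are detected before
filtering and the flags carried over to the filtered data.

Component-based ocular/muscle cleanup (ICA with an automated classifier)
is out of scope; `ica_hook` accepts an arbitrary `EpochSet -> EpochSet`
cleaner so externally cleaned data can be substituted at that stage.
Common-average referencing subtracts the instantaneous scalp mean
(EOG excluded) and is idempotent.

## Time-frequency analysis

The trial decomposition is a short-time Fourier transform with a fixed
500 ms Hanning taper stepped every 100 ms, evaluated directly at integer
frequencies 1–40 Hz (window length fixed rather than cycles per
frequency). The output grid −3.1…+2.2 s leaves the retained ±300 ms of
each epoch purely as padding. Power is normalised so a unit-amplitude
sinusoid yields a taper-independent scale; all downstream quantities are
relative, so the absolute scale cancels.

Percent-change baselining uses B(ch, f) = the mean of **trial-averaged**
power over −3.1…−2.1 s (trial averaging precedes normalisation; the
alternative — per-trial baselines — is noisier and changes the meaning of
the 10% criterion). Zero baseline power raises an error naming the
offending channel and frequency.

Resting spectra use DPSS multitapers with time-bandwidth product
T·W = 2 s × 2 Hz (7 tapers), averaged over tapers and clean 2 s epochs;
a 3.5 min recording trimmed by 15 s at each end yields 90 epochs.

## Entrainment criterion and spectral peaks

The criterion operates on the percent-change volume averaged over O1, O2,
Oz and the stimulation band (centre ± 1 Hz): passed iff the timecourse
stays ≥ 10% for ≥ 500 ms within −1.1…−0.1 s. With the 100 ms step this
means ≥ 5 contiguous bins; window bins are taken left-inclusive
(−1.1 ≤ t < −0.1, ten bins), so a full-window pass sustains exactly
1000 ms. Entrainment *strength* is the maximum of that timecourse.

IAF/ITF are the electrode-averaged power maxima within 8–12 / 3–7 Hz.
The default electrode set is the nine-channel posterior set (Pz, POz, Oz,
O1, O2, P3, P4, PO3, PO4); a five-channel variant appears in parts of the
literature, so the set is configurable. Ties break toward the lower
frequency and emit a warning. The distance-vs-strength association is a
plain Pearson correlation with a t-based two-sided p; inputs with zero
variance or fewer than three participants are rejected.

## Cluster-based permutation testing

Voxelwise statistics (pooled-variance independent t, paired t, or one-way
F) are thresholded at the sample alpha (0.05, strict inequality — a voxel
with p exactly at the threshold is excluded). Suprathreshold voxels
connect along adjacent frequency bins, adjacent time bins, and
neighbouring channels at the same bin (no diagonal connectivity in the
frequency-time plane); positive and negative t-voxels cluster separately
and never merge. Channel neighbourhoods come from a standard 10-05
template montage: channels within 5.5 cm on the template head are
neighbours, the radius widening automatically until no channel is
isolated; the graph serialises to JSON alongside results. No minimum
cluster size is imposed.

The null distribution records, per randomization (subject-label shuffles
for independent designs, within-pair sign flips for paired), the maximum
positive and minimum negative cluster sums separately. Cluster p-values
use (b + 1)/(R + 1), counting the observed labelling in the denominator
so p can never be zero; significance is p < 0.025 per tail for t
(p < 0.05 for the one-sided F). Inside the Monte-Carlo loop the
sample-level threshold is applied to |t| against the critical value
rather than recomputing p-volumes — algebraically identical, several
times faster. With a fixed generator the whole test is bit-reproducible.

## Bayes factors and the sequential design

The two-sample Bayes factor places a Cauchy(0, r = √2/2) prior on the
standardized effect δ under H1 and a point null at δ = 0. With the pooled
t statistic and effective sample size n_eff = (1/n₁ + 1/n₂)⁻¹,

BF₁₀ = ∫ T_df(t; δ√n_eff) dCauchy(δ; 0, r) / T_df(t; 0),

integrated by adaptive quadrature split at δ = 0 (tight tolerances; an
integration-error guard raises rather than returning a doubtful value).
One-sided variants truncate the prior to the predicted half-line and
renormalise (doubling), which gives the identities "one-sided equals
two-sided at t = 0" and "greater + less = 2 × two-sided" — both asserted
in tests, alongside agreement with an independent dense-trapezoid oracle
to 1e-6 relative error and with an external JZS implementation. The
summary-statistic entry point is primary (group M/SD/n are what such
studies print); the raw-vector entry point delegates to it. Equal-variance
pooled t is used throughout.

The published hit-rate contrast is reported two-sided: recomputing both
variants from the printed summaries shows the two-sided value matching
the published Bayes factor and the directional value being almost exactly
twice it, so the two-sided test is what the acceptance script reports.

The sequential monitor evaluates the BF at every look from k = 15,
stopping at the first crossing of BF₁₀ ≥ 3 (accept H1) or ≤ 1/3
(accept H0), or at k = 35 (`max_n_reached`). Looks must be contiguous
in k. Bayesian ANOVAs (one-way and mixed designs) are out of scope; the
pipeline reports descriptive group summaries where a full analysis would
print ANOVA Bayes factors.

## Signal-detection scoring

Hits/misses/correct rejections/false alarms are pooled across runs
(per-run-then-average is the unstated alternative); trials without a
response in the 3 s window are excluded from denominators. Rates at 0 or
1 get the log-linear correction (c + 0.5)/(n + 1) — applied *only* at the
boundaries, so interior rates are exact counts. d′ = z(hit) − z(FA);
participants with FA > 25% are excluded from inference. The larger
no-entrainment cohort (k = 45) is reduced to the entrainment group size
by drawing exactly 50 random subsamples without replacement and keeping
the one whose mean is closest to the full-sample mean (ties to the first
draw); all 50 candidate means are kept for provenance.

## Pipeline and problem sizes

`run_study` applies exclusions in the study's order — entrainment
screening first, then the FA rule, with the overlap tracked separately —
and derives every stochastic stage from one master seed via spawned seed
sequences, so a rerun is bit-identical. Any stage failure aborts with the
stage name; partial outputs remain on disk.

The test suite exercises the machinery at reduced problem sizes chosen to
keep the full run in a few minutes while leaving each check statistically
meaningful: posterior channel subsets (6–9 channels) where the analysis
is occipital anyway, 6–141 trials per participant depending on what the
check needs (the entrainment operating characteristics use the full 141),
8 subjects per group and 500 randomizations for the type-I calibration
(200 replicate cohorts), and 4000 randomizations where a single test is
compared against exhaustive enumeration. File outputs are HDF5 for
arrays, TSV for tables, JSON for reports; EDF/BrainVision reading is
delegated to MNE, and recordings are persisted in a documented HDF5
layout (no EDF writer is bundled).

## Known limitations

- The entrained component mixes entrainment proper and stimulus-locked
  evoked activity by construction; the pipeline cannot (and does not try
  to) separate them.
- The artifact detector's filter settings are calibrated on the synthetic
  noise model, not claimed identical to any toolbox's internals; the
  cutoffs (60/30) are fixed design constants.
- The channel-neighbour template is a generic montage, not a measured
  sensor layout; results serialise the graph so any substitution is
  auditable.
- Unequal-variance SDT, ROC/confidence analyses, reaction-time modelling
  beyond descriptives, and Bayesian ANOVAs are deliberately absent.
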