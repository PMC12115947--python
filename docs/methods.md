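# Methods

## The detection problem

Nine visual stimuli flash one at a time at a 400 ms inter-stimulus interval
(ISI); the user attends one of them. Each attended flash evokes a P300 — a
positive deflection of roughly 5 µV peaking ~300–350 ms post-stimulus —
buried in ongoing EEG an order of magnitude larger. Detection follows the
classical averaging recipe: cut one epoch per flash from 1000 ms before to
500 ms after onset (1501 samples at 1 kHz; both endpoint samples included),
discard epochs whose amplitude leaves ±100 µV anywhere in that extent
(blinks, movement), average the retained epochs per stimulus label, subtract
a pre-stimulus baseline reference, and score each label by the maximum (most
positive) amplitude inside the inclusive post-stimulus window 300–370 ms.
The label with the largest windowed peak is called as the attended target.

The baseline reference is the variable under study. Three strategies are
implemented:

* **single_point** — subtract the amplitude at one instant t_b (Eq.:
  S_corr(t) = S(t) − S(t_b)); the corrected value at t_b is exactly 0.
* **range_average** — subtract the mean over a half-open interval
  [start, end), default [−200, 0) ms.
* **multi_point** — run the single-point classification once per instant of
  a half-open grid over [−200, 0) ms at 1 ms steps (exactly 200 reference
  points), count each label's provisional wins, and return the label with
  the most votes.

### Conventions and tie-breaks

* Sample indices are 0-based; t = 0 is the stimulus-onset sample;
  pre-stimulus times are negative milliseconds.
* All baseline ranges and grids are half-open [start, end). This makes the
  default grid "0 to 200 ms before the stimulus" contain exactly 200 points
  and excludes the onset sample itself, which is stimulus-contaminated by
  definition. The boundary convention is the package's own; one sample
  either way is immaterial at 1 kHz but must be fixed for exact tests.
* The detection window [300, 370] ms is inclusive (71 samples at 1 kHz).
* The peak score is the literal signed maximum, not the maximum absolute
  value — the P300 is a positive deflection.
* Amplitude ties inside a window resolve to the earliest time; amplitude or
  vote ties between labels resolve to the smallest label id and are logged.
  Ties have probability zero for continuous data; the rule exists so that
  degenerate inputs behave deterministically.
* Averages use the first n retained epochs in presentation order
  (sequential-experiment semantics — the state of knowledge after n
  presentations), not a random subset.
* Millisecond-to-sample conversion rounds to the nearest sample and warns
  when rounding occurs, so non-1 kHz rates are supported without silent bias.

### Linearity shortcut

Both corrections subtract a per-epoch constant, so correcting every epoch
and then averaging equals averaging first and correcting the average. The
classifiers use the second form: per-label peaks and per-grid-point baseline
values are computed once from the averaged waveforms, making the 200-point
vote a vectorised subtraction instead of 200 re-averaging passes. The
equivalence is asserted in the test suite at floating-point tolerance, and
it makes the one-point-grid vote *exactly* equal to the single-point
classifier.

## Preprocessing

The continuous recording is high-passed at 0.05 Hz (second-order
Butterworth) before epoching. Filtering is applied forward and backward
(`sosfiltfilt`) for zero net phase shift: a causal filter would delay the
P300 and corrupt the 300–370 ms window logic. The photosensor channel passes
through unfiltered. Amplitude rejection is evaluated after filtering, on the
full epoch extent (pre-stimulus included — baseline integrity is the point);
a switch in `prepare_epochs` (`highpass_hz=None`) lets the user re-order or
skip the filter. Events whose epoch window does not fit inside the recording
are dropped with a warning rather than padded, since padding would fabricate
baseline data.

## Statistical comparison

`compare_methods` performs two-sided Wilcoxon signed-rank tests on paired
per-subject accuracies for every method pair: zero differences dropped
(Wilcoxon's original rule), mid-ranks for tied absolute differences, the
exact signed-rank distribution for n ≤ 25 and the normal approximation with
continuity correction above, Holm step-down adjustment across the pairs, and
effect size r = |Z|/√n with Z from the tie-corrected normal approximation.
These are the conventional completions of "Wilcoxon signed-rank with Holm
adjustment"; the implementation is checked against exhaustive enumeration of
the 2^n sign assignments for n ≤ 8.

## The synthetic oddball session

The generator emulates the stimulation design exactly: balanced pseudo-random
label order with no immediate repeats (greedy weighted draw with a forced
pick at the feasibility boundary, so a valid sequence is always found when
one exists), flash k at `lead_in + k·ISI + ⌊k/36⌋·10 s`, hence the first
rest 14 400 ms into the flash timeline and 3.6 s per nine-stimulus block.
A 2 s lead-in/lead-out gives the first and last epochs their full extent.

The single synthetic channel is a sum of:

* **Background rhythm** — a constant-amplitude sinusoid (default 10 Hz,
  8 µV) whose phase performs a Wiener random walk giving a Lorentzian line
  of 2 Hz full width, a typical eyes-open alpha linewidth. Phase is
  continuous through the whole recording, so epoch-to-epoch phase follows
  the stimulus schedule — the structured pre-stimulus activity that makes
  continuous stimulation hard — rather than being redrawn per epoch. The
  width matters: a mathematically pure 10 Hz sinusoid is phase-locked to the
  400 ms ISI (exactly 4 cycles per ISI, 100 per rest) and would *never*
  average out, making target recovery impossible at any averaging count;
  with a realistic linewidth, epochs 400 ms apart are nearly
  phase-independent and the rhythm cancels as real alpha does, leaving a
  residual of amplitude ≈ A/√(2n) after n averages.
* **1/f broadband noise** — white Gaussian noise shaped to 1/f power above
  1 Hz (flat below), normalised to 8 µV total RMS.
* **P300 bumps** — a Gaussian of 5 µV peak, 330 ms latency, 80 ms FWHM
  added after every attended flash; every injected bump is recorded in a
  ground-truth sidecar.
* **Optional components** — a slow narrowband wander (default 2 Hz, i.e. a
  500 ms period exceeding the 200 ms baseline window, spectral width
  0.1 Hz), blink-like 150 µV Gaussian transients at a Poisson rate, and
  mains interference. The drift's narrow width is essential to the regime it
  models: the wave must stay locally coherent across one epoch (so that
  recent pre-stimulus values genuinely track the reference level near the
  peak, and sliding or widening the baseline window visibly moves the
  measured peak) while decorrelating between same-label epochs seconds
  apart. A wider line decoheres within the epoch and destroys the
  phenomenon.

A clean photosensor channel pulses 5000 (arbitrary units) for the 200 ms
flash duration at every onset. Everything is reproducible bit-for-bit from
one seed (`numpy` `SeedSequence` spawning per subject and run).

### Cohorts and calibration

`generate_cohort` produces 22 independent subjects by default, each with two
runs (targets 3 then 5) sharing per-subject traits drawn uniformly: rhythm
amplitude U(6.5, 9.5) µV, rhythm frequency U(9, 11) Hz, P300 latency
U(315, 345) ms — a desk-scale stand-in for inter-individual variability.

The default rhythm amplitude is calibrated against the behavioural anchor
the generator exists to emulate: at 40-epoch averaging the range-averaged
and multi-point methods identify the target in ≥ 90 % of cohort runs, the
single-point method is clearly worse, and all methods sit near chance at 10
averages. 8 µV satisfies the anchor; the achievable ceiling is ≈ 93 %
because the 8 µV 1/f broadband floor, not the rhythm, then limits the margin
of the 5 µV bump over eight competitors. The rhythm amplitude is exposed, so
harder regimes (e.g. 15 µV, or the ~50 µV raw-EEG scale) remain available.

### Ground-truth recovery measurement

`recover_bump` estimates the injected bump from an averaged target waveform
by least-squares fit of the known Gaussian template over a latency search
range (a matched filter). A raw max-over-window statistic is *not* used for
this purpose: the maximum of signal-plus-noise exceeds the signal's peak in
expectation (≈ +1 µV ≈ +20 % at the default noise levels and n = 100), so it
would report a biased amplitude however faithfully the bump survived
averaging. The template fit is unbiased at the true latency and its latency
estimate is insensitive to narrowband residuals.

### What the generator does not emulate

Real scalp EEG has multi-channel spatial structure, non-Gaussian artifacts,
early visual evoked components after *every* flash (not only targets),
amplitude-modulated (waxing–waning) alpha, and session-scale
non-stationarity. None of these are modelled. Consequently, passing tests
show that the pipeline implements the intended algorithms and reproduces the
qualitative regimes (averaging law, baseline-stability contrasts, slow-wave
degradation) under controlled conditions — not that the quantitative
accuracies transfer to human recordings. In particular, the periodic
pre-stimulus "fluctuation" structure that real continuous stimulation
imprints (each flash's evoked response landing in the next epoch's baseline
region) is present only through the attended-flash bumps.

## Problem sizes

Defaults were chosen so every analysis runs comfortably on one CPU: a full
session is 900 flashes ≈ 10 minutes of 1 kHz signal; the cohort study is 22
subjects × 2 runs; sweeps are vectorised over their grids (1000-point
baseline sweeps take milliseconds once the averages exist). The acceptance
script completes in well under a minute; the test suite in about a minute.

## Known limitations

* One EEG channel; no multi-channel fusion (Fz/Cz/Pz ensembles) or spatial
  filtering.
* The EDF writer is minimal (16-bit, one data record, per-channel physical
  scaling): adequate for round-tripping this package's recordings, not a
  general-purpose EDF library. Reading uses `mne`.
* `correct_*` operate per epoch or on averaged waveforms; no incremental /
  online classification.
* The Wilcoxon machinery targets the small paired cohorts of this design;
  for large samples it simply defers to the normal approximation.
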