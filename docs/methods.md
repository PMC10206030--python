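# Methods

This note documents the models and procedures implemented in `nirscomp`,
the parameter choices that matter, and what the synthetic data can and
cannot establish about real recordings.

## Signal model and synthetic trials

A muscle-NIRS channel is modelled in common-mode / differential-mode
space. The common-mode signal (CMS) represents blood-flow changes, which
move Hb and HbO₂ together; the differential-mode signal (DMS) represents
oxygen consumption, which moves them apart. The chromophore pair is the
exact linear image of this pair:

    Hb = CMS − DMS,    HbO₂ = CMS + DMS.

The clean per-channel response of a trial is a ramp-to-plateau curve:
activation onset at 20 % of the trial, offset at 80 %, logistic ramps
whose transition occupies `rise_time` (default 2 s — hemoglobin
concentration takes a few seconds to reach a new plateau). Amplitudes
come from a per-class, per-channel activation map; the default map places
the dominant response on the executing-side obliquus externus abdominis
for lean-forward and trunk-rotation compensation and on the
executing-side trapezius and erector spinae for shoulder elevation, with
weaker opposite-side involvement. The no-compensation class keeps a
light (0.12–0.15 a.u.) engagement of executing-side stabilisers: it
represents a real uncompensated reaching motion, not rest. Amplitudes
are in arbitrary concentration-change units since the acquisition system
is uncalibrated; the map magnitudes are free parameters of the simulator,
chosen once to give a realistic contrast (peak activation ≈ 20× the
broadband noise floor before filtering).

Artifacts are layered on after the clean mapping, independently per
chromophore series: baseline drift (sinusoid of period 60 s plus a random
linear term, total amplitude 0.3 a.u. — comparable to 30 % of peak
activation), a cardiac sinusoid at 1.2 Hz (0.05 a.u.), Gaussian noise
(sd 0.05 a.u.) and sample drop-outs (probability 0.01 per sample,
stored as NaN plus a boolean mask; the first four samples are always
kept so the padding rule has a valid prefix). Subjects differ by
per-channel lognormal amplitude factors (σ = 0.1). Default trial
duration is 10 s at 16 Hz (a reaching repetition plus surrounding rest);
the default dataset is 6 subjects × 20 trials per class, which yields a
feature matrix of ≈ 14 000 windows — the same order as the study sizes
the analysis targets.

What the simulator does **not** emulate: motion artifacts (optode
shifts, spikes), Beer–Lambert crosstalk between chromophores, fatigue
drift across trials, inter-trial amplitude variability beyond the
subject factor, or stroke-specific asymmetries beyond the activation
map. Passing tests therefore demonstrate that the pipeline recovers the
structure it assumes, not that real recordings satisfy those
assumptions.

## Preprocessing

Order: pad → low-pass → detrend, applied per channel per chromophore.

* **Padding.** Each missing sample is replaced by the mean of the four
  preceding values; already-padded values count, so gaps fill left to
  right. A missing value inside the first `lookback` samples is an
  error (nothing to average).
* **Low-pass.** Sixth-order Butterworth, 0.5 Hz cutoff, applied
  forward–backward as cascaded second-order sections — zero phase, so
  activation timing is preserved for slope analysis. Boundary handling
  is selectable: the default (`edge="ar"`) extends the series on both
  sides by Burg autoregressive extrapolation (AR order ≤ 12, one filter
  settling length of 4/cutoff seconds per side, discarded after
  filtering), which continues oscillatory content smoothly and keeps
  stop-band attenuation at its steady-state level (> 99.99 % RMS at
  2 Hz) right up to the series ends; an unstable extrapolation falls
  back to plain padding. `edge="pad"` is scipy's odd-reflection
  padding — exactly linear in the input, but with a low-frequency edge
  transient that dominates short records. The AR mode is linear away
  from the edges only (the extrapolation model is data-dependent); the
  linearity property is exact in pad mode.
* **Detrending.** EMD by iterative sifting (natural cubic-spline
  envelopes through local extrema, one mirrored extremum per side;
  sifting stops when the normalised squared change drops below 0.2).
  Decomposition continues while the residual still holds a full
  oscillation (at least one maximum and one minimum), and a candidate
  IMF is accepted only if it oscillates about zero (≥ 2 sign changes) —
  otherwise sifting has hit the trend and decomposition stops. The
  baseline is the final residual; subtracting it removes drift while the
  activation response, which oscillates relative to the drift, stays in
  the IMFs. The alternative rule `residual_plus_last_imf` also removes
  the slowest IMF, but on 10 s trials the activation plateau is itself
  the lowest-frequency oscillatory component, so that rule deletes the
  signal whenever few IMFs exist; it is therefore not the default and is
  applied only when at least two IMFs were extracted. A monotone or
  constant series (nothing to sift) falls back to removing its own
  linear fit, with a warning.

## Signal improvement

CBSI assumes perfect Hb–HbO₂ anti-correlation: α = std(HbO₂)/std(Hb)
(population convention, per channel per trial), TNS = ½(HbO₂ + α·Hb),
TFS = ½(HbO₂ − α·Hb). DBSI needs no assumption: CMS = ½(HbO₂ + Hb),
DMS = ½(HbO₂ − Hb), an invertible linear map whose inverse doubles as
the simulator's forward model — which is what makes stage-wise ground
truth possible.

## Activation segmentation

The linear fitting slope of a window is the ordinary least-squares slope
of the signal against time. (The printed closed form this statistic is
sometimes given in mixes signal and time sums and is dimensionally
inconsistent; the OLS slope is the evident intent and is what is
implemented.) Windows of 8 samples with stride 4 give per-window slopes
LFSₘⁿ. Detection:

1. Quiescence threshold `tol_zero` = max(3 × median |window slope| over
   the first second of the trial, 0.05 × peak |window slope|). The
   first term adapts to the noise floor (the trial starts at rest); the
   floor term keeps a noise-free rest period from collapsing the
   threshold to numerical zero, and encodes that slopes below 5 % of the
   trial's peak rate count as quiescent.
2. Consecutive windows with the same above-threshold sign form a
   candidate run; the run is active when the mean of its window slopes
   agrees with the slope fitted over the entire run within a relative
   tolerance of 0.5 and that run slope itself exceeds `tol_zero`.
3. Rising runs are `active_up`, falling runs `active_down`; the rest of
   the trial is `inactive`. Segments are clipped to a non-overlapping,
   ordered cover of the trial.

Both tolerances are configurable; "approximately equal" is not
quantified by the source analysis, so these are detector design choices,
fixed before evaluation. On noise-free trials the detected ramps overlap
the true logistic ramps with Jaccard ≈ 0.8 (the logistic tails extend
the detected interval symmetrically).

An **activated span** runs from a rising segment's start to the end of
the next falling segment: the plateau between activation and
deactivation is part of the activated state (it is what the
activation-segment box plots of the underlying analysis summarise).
Unpaired rising/falling segments — typically spurious single-run
detections — contribute no span.

## Features and classification

Per window, per channel, per improved series: MEA (mean) and STD
(population standard deviation, divisor k). The full configuration gives
24 columns in a fixed channel-major order; single-component sets (TNS,
TFS, CMS or DMS alone) give 12. `extract_features` defaults to dense
windowing (every window fully inside the trial); the pipeline's
evaluation path restricts windows to activated spans (union over
channels and series), since features are meant to describe the active
segments — dense windowing dilutes every class with identical rest
windows and caps attainable accuracy well below the active-window
protocol.

The classifier is a one-vs-one RBF SVM, C = 0.3, RBF width 1/(n_features
· Var) on the normalised training rows. Ten-fold cross-validation is
stratified by class; normalisation (z-score default) is fitted on each
fold's training rows only and applied to the held-out rows, so scaling
leaks nothing. Splitting defaults to the window level, mirroring the
random sample-level protocol of the source analysis; note that
window-level splits place temporally adjacent, overlapping windows of
the same trial on both sides of the split, which inflates accuracy
relative to trial- or subject-level splits — both of which are available
via `split_unit`. Reports carry both the mean of fold accuracies and
the pooled-confusion accuracy, since either averaging convention is
defensible. Class order NC < LF < TR < SE is the documented encoding
and tie-break order.

## Numerical and degenerate-input choices

* Missing samples are NaN sentinels plus an explicit mask; the mask
  survives preprocessing as provenance of interpolated samples.
* CBSI on a constant Hb channel is an error (α undefined); zero-variance
  features are mapped to 0 with a warning during normalisation;
  zero-denominator precision/recall are reported as 0 with a warning.
* Trial CSVs are written with 9 significant digits; identical seeds and
  configs reproduce byte-identical CSV and JSON outputs.
* The permutation-null check runs on a stratified 4 000-row subsample of
  the feature matrix: chance level does not depend on sample size, and
  an RBF SVM on shuffled labels of the full matrix has no margin
  structure to exploit, making it disproportionately expensive.

## Known limitations

* EMD detrending on 10 s windows cannot separate drift components whose
  period is comparable to the activation plateau; the simulator's drift
  (60 s period) is safely slower, real drift need not be.
* The window-level CV default reproduces a protocol with known temporal
  leakage; subject-level generalisation claims require
  `split_unit="subject"`.
* Simulator amplitudes, and hence all absolute accuracies on synthetic
  data, are free parameters; only orderings and contrasts (e.g. DBSI ≥
  raw, TFS weakest, CMS > DMS) should be compared across signal types.
* The healthy/stroke distinction is metadata only; both groups share the
  same generative model apart from the configuration supplied.
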