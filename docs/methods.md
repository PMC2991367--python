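# Methods

This note records the model, the numerical choices, and the design
decisions behind `matchedpsc`, in the spirit of a methods appendix: what
the procedure assumes, which knobs matter, and what the synthetic
benchmark does and does not establish.

## Signal model and assumptions

A voltage-clamp trace is modeled as a sum of inward synaptic events,
an optional slow direct uncaging response beginning at the laser onset,
and additive background noise. Events are monophasic, fast-rising and
slower-decaying; their waveforms vary trial to trial, which is why a
*bank* of templates rather than a single one is used. The matched filter
is the SNR-optimal detector for a known waveform in noise; with the
waveform only approximately known, convolving with several
human-validated templates and taking threshold crossings approximates it.
Outward (IPSC) recordings are sign-inverted so one pipeline serves both
polarities.

## Training stage

- Marked segments are baseline-anchored at their onset value before
  fitting. The onset value, not a fitted baseline, is the amplitude
  reference throughout.
- The polynomial fit (default order 8) is solved on a time axis rescaled
  to [−1, 1] for conditioning; the fitted waveform is evaluated at the
  original sample times and divided by its L1 norm, making templates
  amplitude-free. Order 8 is adequate for ~14 ms compound events sampled
  at 10 kHz; higher orders overfit.
- `c_max` is the maximum of the full (zero-padded) convolution of the
  baseline-anchored raw segment with its template. Anchoring matters: a
  holding-current DC offset would otherwise dominate the convolution
  through the template's nonzero sum, and the detection stage convolves
  DC-free (high-pass-filtered) data.
- The per-template *shift* — the offset between the convolution maximum
  and the event peak — is calibrated on the high-pass-filtered trace,
  because that is the domain in which the shift is later applied;
  filtering advances an asymmetric event's convolution peak by a fraction
  of a millisecond relative to the raw trace. The shift maps the filtered
  convolution peak onto the raw event peak, the reference for
  localization and measurement.
- Pooled statistics use the sample (n−1) SD: banks are small (10–18
  filters). A bank below 10 filters triggers a warning, not an error.

## Detection stage

- High-pass: 5th-order Butterworth at 10 Hz, applied forward and backward
  (`sosfiltfilt`), so events keep their timing. The filter suppresses the
  direct response and drift; for dense event clusters it also removes
  part of the cluster envelope, slightly reducing apparent event depth —
  one reason detection thresholds are recommended *below* the training
  mean (k ∈ [−1.5, −1]).
- Candidates: per filter, maximal runs above μ + kσ. Each run yields a
  center-of-mass time and, because runs of neighboring events fuse at
  high SNR, one candidate per local maximum of the convolution inside the
  run (spaced ≥ half the mean lead; the run is linearly detrended across
  its endpoints first, so a neighboring event's decaying convolution tail
  does not drag the maxima). Aligned convolution maxima (`t_hat`) are
  clustered across filters with a half-lead gap; the cluster median is
  the bank's consensus occurrence estimate.
- Window gating: candidates inside [laser, laser + W_d) are direct
  responses (W_d = 10 ms); inside [laser + W_d, laser + W_o) they are
  additionally dismissed when any convolution trace exceeds μ + 4σ within
  their run (W_o = 30 ms). After localization, an event whose *onset*
  falls inside the direct window is dismissed as a small direct response;
  retained events with peaks inside the outlier window are flagged as
  over-riding the direct response.
- Peak refinement: troughs of the lightly smoothed (3-point) original
  trace are searched in [t_cm − L, t_cm + T] (bank mean lead/trail), with
  candidate troughs required to be minima over half a mean lead so
  single-sample noise wiggles do not compete. The deepest trough within
  one mean lead of the consensus estimate wins; when no trough lies that
  close, competing peaks are scored on three equally weighted 0–100
  criteria — the number of convolution traces above threshold at the
  peak, the peak amplitude, and the second derivative at the peak
  (Savitzky–Golay over ~one mean lead; a single-sample stencil at 10 kHz
  would measure sampling noise, not peakiness) — earlier peak on ties.
- Onset: the highest-valued point of [t_p − L_on, t_p], where
  L_on = mean lead + (multiplier × SD), floored at the longest lead in
  the bank. A genuine pre-onset crest is that argmax when one exists; on
  a limb that descends monotonically through the window the window-edge
  supremum is the best available onset estimate.
- Offset and overlap splitting: on (t_p, t_p + L_off], no local maxima ⇒
  local supremum. Otherwise each local minimum is tested in time order
  against the highest preceding local maximum p_b: if value(p_b) −
  value(minimum) exceeds the amplitude cutoff *and* the minimum coincides
  with a convolution peak estimate, p_b becomes this event's offset and
  the next event's onset (handed over exactly once); the next event's
  peak is then refined through the normal consensus search. If no minimum
  qualifies, the offset is the highest point among trailing maxima and
  the window end.
- Amplitude gate and measurement: peak amplitude is value(onset) −
  value(peak); events must exceed the cutoff (default: the bank's mean
  spontaneous-EPSC amplitude; 0 disables). Pointwise values are read from
  a 0.5 ms moving average — indices are chosen as extrema of the trace,
  and reading the extreme sample itself would inflate every amplitude by
  the local noise excursion. Rise time is t_p − onset; summed input is
  2 × |∫ (leading limb − onset value)| in pA·ms (the trailing limb of
  events riding a direct response is unreliable); latency is t_p − laser
  onset. Extracted segments are raw samples over [onset, offset] plus a
  configurable margin (default 2 ms).
- Each event is localized once: a peak falling inside an already-claimed
  [onset, offset] interval is the same event re-found through another
  filter. Output is chronological with distinct peak times.

## Synthetic benchmark

The simulator emulates the experimental benchmark libraries:

- **Templates** (default 10): differences of exponentials with rise
  constants drawn from 0.8–1.8 ms and decay constants from 2.2–3.5 ms,
  trimmed to the support above 5% of peak —
  supports of ~8–13 ms (mean ≈ 11 ms), onset-to-peak 1.5–2.5 ms. Each
  waveform has unit peak magnitude, so one SNR (peak over noise SD)
  describes a trial.
- **Noise** (default 20 traces of 400 ms): Gaussian background with a
  mild AR(1) component (φ = 0.3) and a zero-phase 2 kHz low-pass, the
  band limit of a typical acquisition chain; plus spontaneous EPSC-like
  transients at 2 /s with peaks 2–4 × the background SD, the realistic
  false-alarm challenge. Traces are standardized to mean 0, SD 1, and
  the injected transient amplitudes are recorded so the amplitude cutoff
  can be derived from the spontaneous level (mean + 1 SD, rescaled by
  1/SNR) exactly as the training stage would from real data.
- **Event trains**: the event count per 215 ms trial is Poisson at
  20 events/s (mean 4.3). Events are placed uniformly one at a time; a
  placement violating the 27 ms refractory spacing is accepted anyway in
  20% of cases (this produces the overlapping events) and re-drawn
  otherwise. Relocating rather than deleting violators keeps the mean
  count at the Poisson value (≈4.3 per trial, matching the benchmark's
  reported average); sequential thinning, the obvious alternative, would
  delete roughly a third of arrivals at these rates and was rejected for
  that reason.
- **Bank for simulations**: trained on the library templates at amplitude
  scales 0.3–0.7 of the unit test-template peak. Experimental banks are
  trained on typical evoked events, which sit below the largest event —
  the normalization reference of the test templates — and whose spread
  gives the c_max statistics a usable threshold band. The chosen scales
  keep μ − 2σ above the convolution noise floor, so the whole recommended
  band μ − 2σ … μ is exercised meaningfully.
- **Scoring**: greedy one-to-one nearest matching of detected peak times
  to planted template peak times at ±1.5 ms (ties toward the earlier
  truth event). The truth records the actual planted peak times, not the
  nominal Poisson arrivals: the detector estimates the peak, and for
  asymmetric waveforms the template midpoint differs from the peak by
  several milliseconds. Pcd and Pfa are per-trial rates averaged across
  trials; the false-alarm denominator is the per-trial detection count
  (configurable).

At SNR 9 with 25–50-trial batches, the detector reaches Pcd ≈ 0.93–0.95
with Pfa ≤ 0.08 across k ∈ [−2, 0], mean signed arrival-time errors
within ±0.05 ms (SD ≈ 0.45 ms), recovery of both members of 8-ms event
pairs in ≥ 90% of trials, and median amplitude errors ≈ 10%. Residual
Pcd losses are events truncated at trial edges, ultra-close (< 3 ms)
pairs that are physically one compound deflection, and cluster-envelope
attenuation by the high-pass stage. Trial counts in the tests (25–50 per
condition, three replicate library draws for the ROC property) were
chosen to keep the suite quick while holding sampling error well below
the margins being asserted.

### What passing the benchmark does and does not show

The generator reproduces the amplitude-normalized, band-limited,
spontaneous-event-contaminated structure of the benchmark recordings, but
its waveforms are smooth two-exponential shapes: real compound EPSCs are
notchier (favoring the curvature criterion more than here), real noise is
not Gaussian, and real direct responses vary in shape and size in ways
the examples only sketch. Synthetic results therefore validate the
machinery and its calibration logic, not absolute performance numbers on
any particular preparation.

## Mapping conventions

- Analysis window: laser + W_d to laser + 150 ms by default,
  configurable; the spontaneous baseline is the same statistic over a
  pre-stimulus window, length-normalized, subtracted per site.
- Site input amplitude: Σ summed-input of in-window events / window
  length (pA), baseline-subtracted. Count and first-latency layers as
  named; missing sites are NaN.
- Group tables: per-cell medians of amplitude, rise time and per-site
  first latency, mean per-site event frequency (in-window count / window
  duration averaged over sites with events), then mean ± SE across cells.
  Pooled-event medians are available behind a flag; per-cell is the
  default because cells, not events, are the experimental unit.

## Known limitations

- No baseline-drift modeling beyond the high-pass stage, no adaptive
  thresholds, no event classification beyond polarity.
- Overlaps closer than ~3 ms are detected as a single compound event by
  construction; amplitudes of split second events are measured from the
  inter-event boundary and underestimate the isolated amplitude.
- The high-pass stage attenuates dense event clusters' envelopes;
  thresholds at or above μ lose sensitivity there.
- Serialization stores full per-template waveforms in JSON; banks are
  small, so compactness was not a goal.
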