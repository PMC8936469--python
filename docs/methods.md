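# Methods

This note documents the models and numerical choices behind `catrace`:
what each stage computes, which parameters matter, what the synthetic
generator does and does not emulate, and the limitations we know about.

## Preprocessing

Raw input is a matrix of per-ROI mean fluorescence (arbitrary units),
`n_rois × n_frames`, at a fixed sampling rate (10 fps typical for
one-photon mini-endoscopes with 100 ms exposure).

**Time binning.** Frames are averaged into non-overlapping bins
(`bin_ms`, default 200 ms → a 10 Hz recording becomes 5 Hz). The bin
width must be an integer multiple of the frame period; a trailing
incomplete bin is dropped rather than padded, so the last output bin is
never a biased mean of fewer samples.

**Background.** A user-supplied scalar or per-frame trace (e.g. a dark
ROI) is subtracted from the raw fluorescence before normalisation by
default. No automatic background estimation is attempted; the
subtraction can alternatively be applied to the ΔF/F₀ traces
(`background_stage="dff"`) for workflows that estimate background on the
normalised signal.

**ΔF/F₀.** Per ROI, F₀ is a global statistic of that ROI's whole trace
and the output is (F − F₀)/F₀. The default statistic is the **median**:
with sparse transients (≈10% of frames carry signal at 1 event/min with a
~1 s decay) the median of the trace sits within a fraction of a percent
of the true baseline, whereas a low percentile sits systematically below
it by about `z_p × noise SD` (≈1.3 σ for the 10th percentile), which
inflates every downstream amplitude by ~25% at typical noise levels. The
10th-percentile baseline remains available (`global_percentile`) for
traces with slow baseline decay where the median would overshoot; the
choice and the fitted F₀ values are recorded in the output metadata.
F₀ ≤ 0 is rejected with the ROI named, since it indicates un-offset or
over-corrected data.

## Event detection

Each ΔF/F₀ trace is scanned in `n_passes` passes (default 3). Pass *p*
computes μ and σ (population denominator *n*) over the samples not yet
claimed by passes 1..*p*−1 and thresholds at **μ + k·σ** (k = 2.5). The
mean offset matters: a bare k·σ is not a meaningful cutoff on un-centred
traces. Every maximal run of unclaimed samples strictly above the
threshold yields one candidate event whose peak is the run's maximum
sample (earliest frame on ties); all supra-threshold samples — including
runs too short to count as events — are removed from the statistics of
later passes, so σ shrinks and smaller peaks become detectable. A trace
with σ = 0 yields no events (constant traces are silent, not all-event).
Both alternative readings of the iteration are configurable: a bare-σ
threshold (`include_mean=False`) and frozen first-pass statistics
(`recompute_stats=False`).

**Minimum run length.** `min_run_frames` defaults to **2** on the 200 ms
timebase: an event must stay above threshold for ≥400 ms. A GCaMP6s
transient (~1 s decay) essentially always does; an isolated white-noise
excursion essentially never does. This single constraint is what keeps
the iterated threshold usable on noisy data — because the pass
statistics converge towards the noise distribution, single-bin
exceedances occur at a rate of a few percent of frames and would
otherwise contribute ~2.4 spurious events/min on pure-noise traces
(measured), swamping a 1 event/min signal. With the default, the
measured pure-noise floor is ~0.03 events/min, dominated by rare
double-bin coincidences. Set `min_run_frames=1` to reproduce the
unconstrained behaviour.

**Refractory filter.** Candidates pooled over all passes are filtered so
that no two retained peaks of one ROI are closer than `refractory_s`
(default 2 s). Selection is greedy by descending amplitude (ties: earlier
peak, then lower pass level), which preserves the most salient transient
and makes the result independent of detection order. Filtering each pass
level separately (`refractory_mode="per_pass"`) is available but does not
guarantee the global separation.

## Session metrics

**Frequency** is 60·n/duration per ROI, averaged over ROIs with equal
weight per cell — silent cells pull the session mean down rather than
being dropped. **Amplitude** is the mean ΔF/F₀ at the retained peaks; an
eventless session reports it as missing, never 0.

**Synchronicity** quantifies population co-activity. Peaks are dilated by
±`window_frames` (default 0 in the metric itself; the pipeline default is
1 bin = ±200 ms, because photometric noise jitters the detected peak of a
shared transient by about one bin). Two summaries are provided:

- `cluster` (default): contiguous stretches of frames where ≥1 cell is
  active form one *population event*; the metric is the mean over
  population events of the percentage of ROIs contributing a peak. It is
  100 exactly when every cell joins every population event and tolerates
  within-window jitter.
- `frame`: the mean over active frames of the co-active cell percentage —
  the strictly frame-wise reading. Under peak jitter it cannot saturate
  (a fully synchronous population event spreads over ~3–5 frames whose
  flanks are only partially occupied), so it systematically understates
  full synchrony; it is retained for comparability.

Both summaries agree whenever active frames are isolated, return 0 for an
eventless session, and are bounded in [0, 100].

**Trajectories and tests.** Same-day replicate sessions (recordings are
typically taken twice per day) are averaged into daily values before
anything longitudinal. Trajectories are long-format per-animal series
ordered by day with phases constrained to baseline → stimulation →
post-stimulation; optional normalisation expresses each metric as % of
the animal's baseline-day mean (absolute values are always kept). Day
pairs are compared with a classical two-tailed paired Student t test,
d = day_b − day_a, t = d̄/(s_d/√n), n−1 df; degenerate inputs (fewer than
two pairs, zero-variance differences) are rejected explicitly rather
than returning a meaningless statistic. No multiple-testing correction is
applied across the three metrics.

## Synthetic recordings

The generator emulates the study conditions the analysis is meant for:
10-minute sessions at 10 fps, 10–100 ROIs, sparse partially-synchronised
transients.

- **Transient kernel**: k(t) = e^(−t/τ_d) − e^(−t/τ_r), τ_r = 0.2 s,
  τ_d = 1.0 s (GCaMP6s-like), truncated below 0.1% of peak and scaled to
  a discrete maximum of exactly 1, so the amplitude parameter equals the
  peak ΔF/F₀ contribution.
- **Event structure**: a shared population schedule is a Poisson process
  (rate defaulting to the per-ROI rate); each ROI joins each shared event
  with probability `sync_prob` and adds a private Poisson stream at rate
  `event_rate × (1 − sync_prob)`, keeping the expected per-ROI rate fixed
  while `sync_prob` moves events between private and population-wide.
  Defaults: 1 event/min, `sync_prob` 0.5.
- **Amplitudes**: normal (mean 0.25, SD 0.05 ΔF/F₀) truncated positive —
  SNR 5 against the noise floor.
- **Noise and drift**: white Gaussian noise (SD 0.05 ΔF/F₀ at the raw
  frame rate) and a slow sinusoid (default 2 fluorescence units ≈ 2% of
  F₀, 120 s period, random phase) that stresses the baseline estimator.
  Raw fluorescence is F = F₀·(1 + signal) with per-ROI F₀ ~ N(100, 10).
- **Phase schedules**: stimulation/post-stimulation days scale event rate
  and `sync_prob` (clamped to [0, 1]) by per-phase multipliers; amplitude
  parameters are never scaled, mirroring a manipulation that changes how
  often and how coherently cells fire but not transient size.

Not emulated: shot noise and photon statistics, motion artefacts,
neuropil contamination, cross-ROI crosstalk, photobleaching ramps, or any
video-level effect — the generator starts where ROI extraction ends.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under idealised noise, not robustness to segmentation or motion
errors in real recordings.

## Validation results and chosen problem sizes

Numbers measured by the test suite and `scripts/acceptance.py` (all
simulated at run time):

- Event-rate recovery, full pipeline, 10-ROI 10-minute sessions, 20 seeds
  per rate: within ±15% of 0.5, 1, and 2 events/min (typically +2% at
  0.5/min and −9 to −14% at 1–2/min; the negative bias at higher rates is
  refractory/run-merge censoring of events closer than ~2–3 s, inherent
  to any refractory-filtered detector).
- Pure-noise false-positive floor: ~0.03 events/min.
- Amplitude recovery at SNR 5: within ±10% of the simulated mean
  (typically +5 to +7%; reading the run maximum as the amplitude is
  upward-biased by the expected maximum of the noise over the few
  near-peak frames).
- Synchronicity rises strictly with `sync_prob` (e.g. ≈6 → 7 → 9 → 16 →
  74% over 0 … 1 with 20 ROIs). At `sync_prob = 1` the cluster summary
  measures ~75–80% rather than ~100%: detection per se is essentially
  perfect there (every ROI, every shared event), but the handful of
  residual double-bin noise detections form singleton population events,
  and with only ~10 true population events per session an
  equally-weighted per-event mean is diluted by each of them. This is a
  known limitation of combining a small number of population events with
  a per-event participation average.
- Effect structure, 5 animals, 2 baseline + 2 stimulation imaging days,
  2 sessions/day, 8 ROIs, 0.6× stimulation multipliers on rate and
  synchrony: paired t tests detect decreases in frequency and
  synchronicity in ≥90% of replicates while amplitude stays at the
  nominal false-positive rate; a null simulation rejects at ~5%.

Problem sizes in the suite (10–20 seeds per condition, 8–20 ROIs, 2+2
imaging days for the power simulation) were chosen as the smallest that
keep Monte-Carlo error well below the tolerances being asserted.

## Numerical conventions

- Population (denominator n) SD for detection thresholds; sample
  (denominator n−1) SD inside the paired t test.
- Earliest frame wins ties for a run's peak; amplitude ties in the
  refractory filter resolve to the earlier peak, then the lower pass
  level.
- Frames are 0-based, runs are half-open `[start, end)`,
  `peak_time = peak_frame / sampling_rate` on the post-binning timebase.
- Event frequency uses the declared session duration (e.g. 600 s), not
  the frame count, so dropped trailing bins do not inflate rates.
- Seeded `numpy` Generators everywhere; a population simulation is a
  single sequential stream per seed, and multi-session experiments draw
  per-session sub-seeds from one master generator, so every result is
  bit-reproducible from one integer.
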