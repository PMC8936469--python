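# catrace

Calcium transient detection and population-activity metrics for
one-photon (mini-endoscopic) ROI fluorescence recordings.

`catrace` is for experimenters who have already extracted per-cell mean
fluorescence traces (e.g. GCaMP6s signals from striatal neurons imaged
through a GRIN lens at 10 fps) and need a reproducible, scriptable version
of the classic threshold-based analysis chain:

1. **Preprocessing** — time-averaging into 200 ms bins, optional
   background subtraction, and ΔF/F₀ = (F − F₀)/F₀ normalisation with a
   robust per-ROI global baseline (median by default, low percentile
   selectable).
2. **Event detection** — iterative SD thresholding: on each pass the
   threshold is μ + k·σ (k = 2.5 by default) of the samples not yet
   claimed, each maximal supra-threshold run becomes one event (peak = run
   maximum), and detected samples are removed before the statistics of the
   next pass, letting smaller transients surface once large ones no longer
   inflate σ. Three passes by default, followed by a 2-second refractory
   filter that keeps the larger peak when two collide.
3. **Population metrics** — per-session event frequency (events/min,
   cell-weighted), mean event amplitude (ΔF/F₀), and synchronicity (the
   percentage of cells participating in the same population event, with a
   configurable ±w-frame coincidence tolerance).
4. **Longitudinal statistics** — per-animal trajectories across a
   baseline → stimulation → post-stimulation timeline, optional
   normalisation to each animal's baseline mean, and two-tailed paired
   Student t tests between imaging days.
5. **Synthetic ground truth** — a generator of realistic recordings
   (double-exponential GCaMP6s-like transients, thinned shared Poisson
   schedule for partial synchrony, white photometric noise, slow baseline
   drift) so that every stage can be validated end to end against known
   event times, rates, and synchrony levels.

## Worked example

```python
import numpy as np
from catrace import (PopulationSimParams, SessionInfo, PipelineConfig,
                     simulate_population)
from catrace.pipeline import process_session

# a 10-minute, 10 fps session of 20 ROIs, ~1 event/min, half of the
# events drawn from a population-wide schedule
params = PopulationSimParams(n_rois=20, seed=7)
tm, truth = simulate_population(
    params, SessionInfo(animal_id="m1", day=1, phase="baseline"))

dff, raster, m = process_session(tm, PipelineConfig())
true_rate = 60 * np.mean([len(v) for v in truth.roi_events.values()]) / 600
print(f"true rate      : {true_rate:.2f} events/min per ROI")
print(f"detected       : {raster.n_events} events in {raster.n_rois} ROIs")
print(f"frequency      : {m.frequency_per_min:.2f} events/min per ROI")
print(f"mean amplitude : {m.mean_amplitude:.3f} dF/F0 (simulated mean 0.25)")
print(f"synchronicity  : {m.synchronicity_pct:.1f} % (sync_prob 0.5)")
```

prints

```
true rate      : 1.31 events/min per ROI
detected       : 249 events in 20 ROIs
frequency      : 1.25 events/min per ROI
mean amplitude : 0.268 dF/F0 (simulated mean 0.25)
synchronicity  : 11.5 % (sync_prob 0.5)
```

i.e. the detector recovers the realised event rate within a few percent,
reads amplitudes with a small positive peak bias, and the synchronicity
metric reflects that only half of the events are population-wide (private
events dilute the per-event participation average).

## Command line

Each stage is also a subcommand of the `catrace` CLI:

```sh
catrace simulate --n-rois 30 --duration-s 600 --fps 10 --rate-per-min 1 \
        --sync-prob 0.5 --seed 7 --out traces.csv --truth truth.json
catrace detect --input traces.csv --fps 10 --bin-ms 200 --k-sd 2.5 \
        --passes 3 --refractory-s 2 --out events.csv
catrace metrics --events events.csv --session-meta sessions.csv --out metrics.csv
catrace trajectory --metrics metrics.csv --normalize-baseline --out trajectory.csv
catrace compare --metrics metrics.csv --day-a 3 --day-b 9 --out tests.csv
catrace reproduce-timeline --seed 1 --out-dir results/
```

`reproduce-timeline` chains everything: it simulates a cohort of animals
imaged every second day through baseline, stimulation (event rate and
synchrony scaled by 0.6, amplitude untouched), and post-stimulation
phases, runs the full analysis, and writes the metrics, trajectory, and
paired-comparison tables.

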