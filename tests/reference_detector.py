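"""Independent brute-force reference implementation of the event detector.

Written with plain Python loops and no shared code with the package: each
pass recomputes the mean and population SD from scratch over the samples
not yet removed, scans for maximal supra-threshold runs by exhaustive
linear search, and the refractory filter is the same greedy
largest-amplitude-first rule.  Used as the oracle for equivalence tests.
"""

from __future__ import annotations

import math


def brute_force_detect(
    trace,
    sampling_rate,
    k_sd=2.5,
    n_passes=3,
    refractory_s=2.0,
    min_run_frames=1,
    include_mean=True,
):
    """Return a list of event dicts sorted by peak frame."""
    x = [float(v) for v in trace]
    n = len(x)
    removed = [False] * n
    candidates = []
    for level in range(1, n_passes + 1):
        kept_vals = [x[i] for i in range(n) if not removed[i]]
        if len(kept_vals) < 2:
            raise ValueError("over-excluded trace")
        mu = sum(kept_vals) / len(kept_vals)
        var = sum((v - mu) ** 2 for v in kept_vals) / len(kept_vals)
        sd = math.sqrt(var)
        if sd == 0.0:
            continue
        thr = mu + k_sd * sd if include_mean else k_sd * sd
        i = 0
        while i < n:
            if (not removed[i]) and x[i] > thr:
                start = i
                while i < n and (not removed[i]) and x[i] > thr:
                    i += 1
                end = i
                for j in range(start, end):
                    removed[j] = True
                if end - start >= min_run_frames:
                    peak = start
                    for j in range(start, end):
                        if x[j] > x[peak]:
                            peak = j
                    candidates.append(
                        {
                            "peak_frame": peak,
                            "peak_time_s": peak / sampling_rate,
                            "amplitude": x[peak],
                            "pass_level": level,
                            "run_start": start,
                            "run_end": end,
                        }
                    )
            else:
                i += 1
    order = sorted(
        candidates,
        key=lambda e: (-e["amplitude"], e["peak_time_s"], e["pass_level"]),
    )
    kept = []
    for ev in order:
        if all(
            abs(ev["peak_time_s"] - o["peak_time_s"]) >= refractory_s
            for o in kept
        ):
            kept.append(ev)
    kept.sort(key=lambda e: (e["peak_time_s"], e["pass_level"]))
    return kept


def as_tuples(events):
    """Canonical comparison form for either implementation's events."""
    out = []
    for e in events:
        if isinstance(e, dict):
            out.append(
                (
                    e["peak_frame"],
                    e["pass_level"],
                    e["run_start"],
                    e["run_end"],
                    round(e["amplitude"], 12),
                )
            )
        else:
            out.append(
                (
                    e.peak_frame,
                    e.pass_level,
                    e.run_start,
                    e.run_end,
                    round(e.amplitude, 12),
                )
            )
    return out
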