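"""Iterative SD-threshold detection of calcium transients.

The detector makes several passes over each ΔF/F0 trace.  On every pass it
computes a threshold of ``mean + k·SD`` from the samples not yet claimed by
earlier passes, takes every maximal run of samples strictly above the
threshold as one candidate event (peak = the run's maximum), and removes
the supra-threshold samples from the statistics of subsequent passes.
Removing detected transients shrinks the SD, so later passes can pick up
smaller peaks that the first threshold hid.  A refractory filter then
enforces a minimum separation between retained peaks of the same ROI,
keeping the larger-amplitude peak when two collide.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .trace_model import DffMatrix, SessionInfo

__all__ = [
    "DetectionParams",
    "CalciumEvent",
    "EventRaster",
    "detect_pass",
    "detect_events",
    "apply_refractory",
    "detect_session",
]


@dataclass(frozen=True)
class DetectionParams:
    """Configuration of the multi-pass threshold detector.

    Parameters
    ----------
    k_sd:
        Threshold multiplier: threshold = mean + ``k_sd`` × SD of the
        currently unclaimed samples (population SD, denominator n).
    n_passes:
        Number of successive threshold applications.
    refractory_s:
        Minimum separation (seconds) between retained peaks of one ROI.
    min_run_frames:
        Minimum length of a supra-threshold run for it to count as an
        event.  On a 200-ms binned timebase the default of 2 requires a
        transient to stay above threshold for at least 400 ms, which a
        slow indicator like GCaMP6s always does while single-bin noise
        excursions do not.  Sub-minimum runs are still removed from the
        statistics of later passes.
    include_mean:
        If False the threshold is a bare ``k_sd × SD`` with no mean offset
        (only meaningful for traces already centred on zero).
    recompute_stats:
        If False, every pass reuses the mean/SD of the full original trace
        instead of recomputing them on the unclaimed samples (which makes
        passes after the first redundant); exposed so both readings of the
        iterative scheme can be reproduced.
    refractory_mode:
        ``"pooled"`` (default) applies the refractory filter once to the
        events pooled across passes; ``"per_pass"`` filters each pass
        level independently.
    """

    k_sd: float = 2.5
    n_passes: int = 3
    refractory_s: float = 2.0
    min_run_frames: int = 2
    include_mean: bool = True
    recompute_stats: bool = True
    refractory_mode: str = "pooled"

    def __post_init__(self) -> None:
        if not self.k_sd > 0:
            raise ValueError("k_sd must be positive")
        if self.n_passes < 1:
            raise ValueError("n_passes must be at least 1")
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be non-negative")
        if self.min_run_frames < 1:
            raise ValueError("min_run_frames must be at least 1")
        if self.refractory_mode not in ("pooled", "per_pass"):
            raise ValueError("refractory_mode must be 'pooled' or 'per_pass'")


@dataclass(frozen=True)
class CalciumEvent:
    """One detected transient.

    ``peak_frame`` indexes the (post-binning) timebase, 0-based;
    ``[run_start, run_end)`` is the supra-threshold segment that produced
    the event; ``pass_level`` records which threshold application found it.
    """

    roi_id: str
    peak_frame: int
    peak_time_s: float
    amplitude: float
    pass_level: int
    run_start: int
    run_end: int

    def __post_init__(self) -> None:
        if not self.run_start <= self.peak_frame < self.run_end:
            raise ValueError("peak_frame must lie inside [run_start, run_end)")


def _find_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) intervals of the True runs of a 1-D mask."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_pass(
    dff_trace: Sequence[float] | np.ndarray,
    excluded: np.ndarray | None = None,
    k_sd: float = 2.5,
    *,
    min_run_frames: int = 1,
    include_mean: bool = True,
    sampling_rate: float = 1.0,
    roi_id: str = "",
    pass_level: int = 1,
    stats_excluded: np.ndarray | None = None,
) -> tuple[list[CalciumEvent], float, np.ndarray]:
    """One thresholding pass over a single ΔF/F0 trace.

    Returns ``(events, threshold, new_excluded)``.  The threshold is
    ``mean + k_sd × SD`` of the non-excluded samples (population SD); each
    maximal run of non-excluded samples strictly above it yields one event
    whose peak is the run's maximum sample (earliest frame on ties).  All
    supra-threshold samples are marked in ``new_excluded`` so later passes
    ignore them; runs shorter than ``min_run_frames`` are excluded too but
    emit no event.  If the SD is zero, no events are returned and the mask
    is unchanged.
    """
    trace = np.asarray(dff_trace, dtype=np.float64)
    if trace.ndim != 1:
        raise ValueError("dff_trace must be 1-D")
    if excluded is None:
        excluded = np.zeros(trace.shape, dtype=bool)
    else:
        excluded = np.asarray(excluded, dtype=bool)
        if excluded.shape != trace.shape:
            raise ValueError("excluded mask must match the trace length")
    stats_mask = excluded if stats_excluded is None else np.asarray(
        stats_excluded, dtype=bool
    )
    usable = ~stats_mask
    if usable.sum() < 2:
        raise ValueError(
            "fewer than 2 non-excluded samples left; the trace is "
            "over-excluded and pass statistics are undefined"
        )
    vals = trace[usable]
    mu = float(vals.mean())
    sd = float(vals.std())  # population denominator n
    threshold = mu + k_sd * sd if include_mean else k_sd * sd
    if sd == 0.0:
        return [], threshold, excluded.copy()
    above = (~excluded) & (trace > threshold)
    new_excluded = excluded | above
    events: list[CalciumEvent] = []
    for start, end in _find_runs(above):
        if end - start < min_run_frames:
            continue
        seg = trace[start:end]
        peak = start + int(np.argmax(seg))  # argmax: earliest frame on ties
        events.append(
            CalciumEvent(
                roi_id=roi_id,
                peak_frame=peak,
                peak_time_s=peak / sampling_rate,
                amplitude=float(trace[peak]),
                pass_level=pass_level,
                run_start=int(start),
                run_end=int(end),
            )
        )
    return events, threshold, new_excluded


def apply_refractory(
    events: Iterable[CalciumEvent], refractory_s: float
) -> list[CalciumEvent]:
    """Enforce a minimum separation between retained peaks of one ROI.

    Greedy selection by descending amplitude (ties broken by earlier peak,
    then lower pass level): an event is kept iff its peak lies at least
    ``refractory_s`` from every already-kept peak.  Output is sorted by
    time; all pairwise separations of kept peaks are ≥ ``refractory_s``.
    """
    ordered = sorted(
        events, key=lambda e: (-e.amplitude, e.peak_time_s, e.pass_level)
    )
    kept: list[CalciumEvent] = []
    for ev in ordered:
        if all(
            abs(ev.peak_time_s - other.peak_time_s) >= refractory_s
            for other in kept
        ):
            kept.append(ev)
    return sorted(kept, key=lambda e: (e.peak_time_s, e.pass_level))


def detect_events(
    dff_trace: Sequence[float] | np.ndarray,
    sampling_rate: float,
    params: DetectionParams | None = None,
    roi_id: str = "",
) -> list[CalciumEvent]:
    """Run the full multi-pass detector on one ΔF/F0 trace.

    Passes 2..n see pass statistics with the samples claimed by earlier
    passes removed; events are pooled across passes with their pass level
    recorded, refractory-filtered, and returned sorted by peak frame.
    """
    params = params or DetectionParams()
    trace = np.asarray(dff_trace, dtype=np.float64)
    excluded: np.ndarray | None = None
    n = trace.shape[0]
    frozen_stats = np.zeros(n, dtype=bool) if not params.recompute_stats else None
    pooled: list[CalciumEvent] = []
    for level in range(1, params.n_passes + 1):
        events, _, excluded = detect_pass(
            trace,
            excluded,
            params.k_sd,
            min_run_frames=params.min_run_frames,
            include_mean=params.include_mean,
            sampling_rate=sampling_rate,
            roi_id=roi_id,
            pass_level=level,
            stats_excluded=frozen_stats,
        )
        pooled.extend(events)
    if params.refractory_mode == "pooled":
        kept = apply_refractory(pooled, params.refractory_s)
    else:
        kept = []
        for level in range(1, params.n_passes + 1):
            kept.extend(
                apply_refractory(
                    [e for e in pooled if e.pass_level == level],
                    params.refractory_s,
                )
            )
        kept.sort(key=lambda e: (e.peak_time_s, e.pass_level))
    return kept


@dataclass(frozen=True)
class EventRaster:
    """All detected events of one session, grouped by ROI."""

    events: tuple[CalciumEvent, ...]
    roi_ids: tuple[str, ...]
    n_frames: int
    sampling_rate: float
    session: SessionInfo | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "roi_ids", tuple(self.roi_ids))
        known = set(self.roi_ids)
        for ev in self.events:
            if ev.roi_id not in known:
                raise ValueError(f"event references unknown ROI {ev.roi_id!r}")
        last: dict[str, float] = {}
        for ev in self.events:
            prev = last.get(ev.roi_id)
            if prev is not None and ev.peak_time_s <= prev:
                raise ValueError(
                    f"peak times must be strictly increasing within ROI "
                    f"{ev.roi_id!r}"
                )
            last[ev.roi_id] = ev.peak_time_s

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def duration_s(self) -> float:
        """Session duration: the declared one if known, else the frame span."""
        if self.session is not None:
            return self.session.duration_s
        return self.n_frames / self.sampling_rate

    def events_for(self, roi_id: str) -> list[CalciumEvent]:
        return [e for e in self.events if e.roi_id == roi_id]

    def peak_matrix(self, window_frames: int = 0) -> np.ndarray:
        """Boolean (n_rois, n_frames) matrix of peak positions.

        With ``window_frames = w > 0`` each peak is dilated to the
        ``±w``-frame window around it (coincidence tolerance).
        """
        mat = np.zeros((self.n_rois, self.n_frames), dtype=bool)
        index = {r: i for i, r in enumerate(self.roi_ids)}
        w = int(window_frames)
        for ev in self.events:
            i = index[ev.roi_id]
            lo = max(0, ev.peak_frame - w)
            hi = min(self.n_frames, ev.peak_frame + w + 1)
            mat[i, lo:hi] = True
        return mat

    def to_dataframe(self):
        """Long-format event table (one row per event)."""
        import pandas as pd

        return pd.DataFrame(
            [dataclasses.asdict(e) for e in self.events],
            columns=[
                "roi_id",
                "peak_frame",
                "peak_time_s",
                "amplitude",
                "pass_level",
                "run_start",
                "run_end",
            ],
        )


def detect_session(
    dff: DffMatrix, params: DetectionParams | None = None
) -> EventRaster:
    """Detect events independently in every ROI of a ΔF/F0 matrix."""
    params = params or DetectionParams()
    all_events: list[CalciumEvent] = []
    for i, roi in enumerate(dff.roi_ids):
        try:
            all_events.extend(
                detect_events(dff.values[i], dff.sampling_rate, params, roi_id=roi)
            )
        except ValueError as err:
            raise ValueError(f"ROI {roi!r}: {err}") from err
    return EventRaster(
        events=tuple(all_events),
        roi_ids=dff.roi_ids,
        n_frames=dff.n_frames,
        sampling_rate=dff.sampling_rate,
        session=dff.session,
    )
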