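"""Session-level population statistics and longitudinal comparisons.

Three summary statistics describe each session: event frequency
(events/min, averaged over ROIs with equal weight per cell), mean event
amplitude (ΔF/F0 at the peaks), and synchronicity — the percentage of
cells participating in the same population event.  Sessions are assembled
into per-animal trajectories over the experimental timeline, optionally
normalised to each animal's baseline, and day pairs are compared with a
classical two-tailed paired Student t test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .event_detection import EventRaster
from .trace_model import PHASES, SessionInfo

__all__ = [
    "SessionMetrics",
    "PairedTestResult",
    "event_frequency",
    "mean_amplitude",
    "synchronicity",
    "session_metrics",
    "build_trajectory",
    "paired_comparison",
    "METRIC_COLUMNS",
]

#: Metric columns of a session-metrics table, in canonical order.
METRIC_COLUMNS = ("synchronicity_pct", "frequency_per_min", "mean_amplitude")


@dataclass(frozen=True)
class SessionMetrics:
    """Summary statistics of one imaging session.

    ``mean_amplitude`` is ``None`` when the session has no events: an
    undefined mean is reported as missing, never as zero.
    """

    synchronicity_pct: float
    frequency_per_min: float
    mean_amplitude: float | None
    n_rois: int
    n_events: int
    session: SessionInfo | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.synchronicity_pct <= 100.0:
            raise ValueError("synchronicity_pct must lie in [0, 100]")
        if self.frequency_per_min < 0:
            raise ValueError("frequency_per_min must be non-negative")
        if self.n_events == 0 and self.mean_amplitude is not None:
            raise ValueError("mean_amplitude must be missing when n_events is 0")


@dataclass(frozen=True)
class PairedTestResult:
    """Two-tailed paired Student t test between two days of imaging."""

    t_statistic: float
    p_value: float
    df: int
    n_pairs: int
    mean_difference: float


def event_frequency(raster: EventRaster) -> tuple[pd.Series, float]:
    """Events per minute, per ROI and as the session (cell-weighted) mean.

    Per ROI the rate is ``60 × n_events / duration_s``; the session value
    is the unweighted mean over ROIs, so cells without events pull the
    mean down rather than being dropped.
    """
    duration = raster.duration_s
    counts = pd.Series(0, index=list(raster.roi_ids), dtype=float)
    for ev in raster.events:
        counts[ev.roi_id] += 1
    per_roi = 60.0 * counts / duration
    per_roi.name = "frequency_per_min"
    return per_roi, float(per_roi.mean())


def mean_amplitude(raster: EventRaster) -> float | None:
    """Arithmetic mean ΔF/F0 amplitude over all events; ``None`` if none."""
    if raster.n_events == 0:
        return None
    return float(np.mean([e.amplitude for e in raster.events]))


def synchronicity(
    raster: EventRaster,
    window_frames: int = 0,
    method: str = "cluster",
) -> float:
    """Percentage of cells co-active in the same population event.

    Peaks are first dilated by ``±window_frames`` (coincidence tolerance
    for one-frame detection jitter; 0 means literally the same frame).

    ``method="cluster"`` (default): frames where at least one cell is
    active are grouped into maximal contiguous population events, and the
    result is the mean over population events of the percentage of ROIs
    contributing a peak to that event.  This saturates at 100 when every
    cell joins every population event, even when peak frames jitter
    within the tolerance window.

    ``method="frame"``: the mean over active frames of
    ``100 × coactive(t) / n_rois`` — the strictly frame-wise reading.

    Both reduce to the same value when active frames are isolated, and
    both return 0 for an eventless session.
    """
    if method not in ("cluster", "frame"):
        raise ValueError("method must be 'cluster' or 'frame'")
    if raster.n_events == 0:
        return 0.0
    dilated = raster.peak_matrix(window_frames)
    coactive = dilated.sum(axis=0)
    active = coactive > 0
    if method == "frame":
        return float(np.mean(100.0 * coactive[active] / raster.n_rois))
    peaks = raster.peak_matrix(0)
    padded = np.concatenate(([False], active, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    fractions = []
    for start, end in zip(edges[::2], edges[1::2]):
        participating = int(np.any(peaks[:, start:end], axis=1).sum())
        fractions.append(100.0 * participating / raster.n_rois)
    return float(np.mean(fractions))


def session_metrics(
    raster: EventRaster,
    window_frames: int = 0,
    sync_method: str = "cluster",
) -> SessionMetrics:
    """Bundle synchronicity, frequency, and amplitude for one session."""
    _, freq = event_frequency(raster)
    return SessionMetrics(
        synchronicity_pct=synchronicity(raster, window_frames, sync_method),
        frequency_per_min=freq,
        mean_amplitude=mean_amplitude(raster),
        n_rois=raster.n_rois,
        n_events=raster.n_events,
        session=raster.session,
    )


def metrics_table(metrics: Iterable[SessionMetrics]) -> pd.DataFrame:
    """One row per session with identity and metric columns."""
    rows = []
    for m in metrics:
        if m.session is None:
            raise ValueError("every SessionMetrics needs session metadata")
        rows.append(
            {
                "animal": m.session.animal_id,
                "day": m.session.day,
                "phase": m.session.phase,
                "replicate": m.session.replicate,
                "duration_s": m.session.duration_s,
                "n_rois": m.n_rois,
                "n_events": m.n_events,
                "synchronicity_pct": m.synchronicity_pct,
                "frequency_per_min": m.frequency_per_min,
                "mean_amplitude": (
                    np.nan if m.mean_amplitude is None else m.mean_amplitude
                ),
            }
        )
    if not rows:
        raise ValueError("no sessions provided")
    return pd.DataFrame(rows)


def daily_means(metrics_df: pd.DataFrame) -> pd.DataFrame:
    """Average same-day replicate sessions into one daily value per metric.

    Recordings are typically acquired twice per day; daily averaging is
    done before any trajectory or paired test.  Missing amplitudes
    (eventless sessions) are skipped by the mean.
    """
    dup = metrics_df.duplicated(subset=["animal", "day", "replicate"])
    if dup.any():
        row = metrics_df[dup].iloc[0]
        raise ValueError(
            f"duplicate session for animal {row['animal']!r}, day "
            f"{row['day']}, replicate {row['replicate']}"
        )
    grouped = (
        metrics_df.groupby(["animal", "day", "phase"], as_index=False)[
            list(METRIC_COLUMNS)
        ]
        .mean()
        .sort_values(["animal", "day"], kind="stable")
        .reset_index(drop=True)
    )
    _check_phase_order(grouped)
    return grouped


def _check_phase_order(daily: pd.DataFrame) -> None:
    order = {p: i for i, p in enumerate(PHASES)}
    for animal, sub in daily.groupby("animal"):
        codes = [order[p] for p in sub.sort_values("day")["phase"]]
        if any(b < a for a, b in zip(codes, codes[1:])):
            raise ValueError(
                f"phases out of order for animal {animal!r}: expected "
                f"{' → '.join(PHASES)} along increasing days"
            )


def build_trajectory(
    metrics: Sequence[SessionMetrics] | pd.DataFrame,
    normalize_baseline: bool = False,
) -> pd.DataFrame:
    """Long-format per-animal trajectory of the three session metrics.

    Replicates within a day are averaged first.  With
    ``normalize_baseline`` each metric value is also expressed as a
    percentage of the mean of that animal's baseline days
    (``normalized_value`` column); absolute values are always reported.
    """
    if isinstance(metrics, pd.DataFrame):
        df = metrics
    else:
        df = metrics_table(metrics)
    daily = daily_means(df)
    long = daily.melt(
        id_vars=["animal", "day", "phase"],
        value_vars=list(METRIC_COLUMNS),
        var_name="metric",
        value_name="value",
    ).sort_values(["animal", "metric", "day"], kind="stable")
    if normalize_baseline:
        base = (
            long[long["phase"] == "baseline"]
            .groupby(["animal", "metric"])["value"]
            .mean()
            .rename("baseline_mean")
        )
        long = long.join(base, on=["animal", "metric"])
        with np.errstate(divide="ignore", invalid="ignore"):
            long["normalized_value"] = np.where(
                long["baseline_mean"] > 0,
                100.0 * long["value"] / long["baseline_mean"],
                np.nan,
            )
        long = long.drop(columns="baseline_mean")
    return long.reset_index(drop=True)


def paired_comparison(
    metric_day_a: Sequence[float], metric_day_b: Sequence[float]
) -> PairedTestResult:
    """Two-tailed paired Student t test between two days.

    Differences are taken as day_b − day_a per animal;
    ``t = mean(d) / (SD_sample(d)/√n)`` with n − 1 degrees of freedom.
    Rejects degenerate inputs (fewer than two pairs, or all differences
    identical, where the test statistic is undefined).
    """
    a = np.asarray(metric_day_a, dtype=np.float64)
    b = np.asarray(metric_day_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = a.shape[0]
    if n < 2:
        raise ValueError("paired t test needs at least 2 pairs")
    d = b - a
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise ValueError(
            "all paired differences are identical (zero variance); "
            "the paired t test is degenerate"
        )
    mean_d = float(d.mean())
    t = mean_d / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return PairedTestResult(
        t_statistic=float(t),
        p_value=p,
        df=n - 1,
        n_pairs=n,
        mean_difference=mean_d,
    )
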