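"""Containers and preprocessing for ROI fluorescence recordings.

A recording session is a matrix of mean-fluorescence traces, one row per
cell-body ROI, sampled at a fixed frame rate (10 fps for a typical
one-photon mini-endoscope).  Preprocessing follows the standard chain for
such data: time-averaging into coarser bins (200 ms by default), optional
background subtraction, and ΔF/F0 normalisation against a per-ROI global
baseline.  All operations are pure: they return new matrices and never
mutate their inputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "PHASES",
    "SessionInfo",
    "TraceMatrix",
    "DffMatrix",
    "PreprocessParams",
    "bin_time_average",
    "subtract_background",
    "compute_dff",
    "preprocess",
]

#: Experimental phases of a longitudinal imaging timeline, in order.
PHASES = ("baseline", "stimulation", "poststimulation")


@dataclass(frozen=True)
class SessionInfo:
    """Identity and timing of one imaging session.

    Parameters
    ----------
    animal_id:
        Subject identifier.
    day:
        Integer day index within the longitudinal experiment.
    phase:
        One of :data:`PHASES` — where the session falls relative to the
        experimental manipulation.
    duration_s:
        Nominal recording duration in seconds (600 s for a standard
        10-minute session).
    replicate:
        Index of the session within its day (recordings are typically
        acquired twice per day).
    """

    animal_id: str = "animal-0"
    day: int = 0
    phase: str = "baseline"
    duration_s: float = 600.0
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(
                f"phase must be one of {PHASES}, got {self.phase!r}"
            )
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")


@dataclass(frozen=True)
class TraceMatrix:
    """Raw ROI fluorescence over frames.

    ``values`` has shape ``(n_rois, n_frames)`` in arbitrary fluorescence
    units; ``roi_ids`` are unique identifiers in row order.
    """

    values: np.ndarray
    sampling_rate: float
    roi_ids: tuple[str, ...]
    session: SessionInfo | None = None

    def __post_init__(self) -> None:
        values = np.array(self.values, dtype=np.float64, copy=True)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (n_rois, n_frames) matrix")
        object.__setattr__(self, "values", values)
        roi_ids = tuple(str(r) for r in self.roi_ids)
        object.__setattr__(self, "roi_ids", roi_ids)
        n_rois, n_frames = values.shape
        if n_rois < 1:
            raise ValueError("at least one ROI is required")
        if n_frames < 2:
            raise ValueError("at least two frames are required")
        if len(roi_ids) != n_rois:
            raise ValueError(
                f"{len(roi_ids)} roi_ids for {n_rois} rows of values"
            )
        if len(set(roi_ids)) != n_rois:
            seen: set[str] = set()
            dup = next(r for r in roi_ids if r in seen or seen.add(r))
            raise ValueError(f"duplicate ROI id {dup!r}")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must all be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration_s(self) -> float:
        """Duration covered by the frames actually present."""
        return self.n_frames / self.sampling_rate


@dataclass(frozen=True)
class DffMatrix(TraceMatrix):
    """ΔF/F0 traces (dimensionless), same layout as :class:`TraceMatrix`.

    ``meta`` records how the baseline F0 was obtained so every downstream
    table can carry full provenance.
    """

    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PreprocessParams:
    """Preprocessing configuration.

    Parameters
    ----------
    bin_ms:
        Width of the time-averaging bin in milliseconds; must be an integer
        multiple of the source frame period.  200 ms halves a 10 fps
        recording to 5 Hz.
    baseline_method:
        ``"global_median"`` (default) or ``"global_percentile"`` — how the
        per-ROI baseline fluorescence F0 is estimated from the whole trace.
    baseline_percentile:
        Percentile used when ``baseline_method == "global_percentile"``.
    background:
        Scalar offset or per-frame trace (fluorescence units) subtracted
        before or after normalisation depending on ``background_stage``.
    background_stage:
        ``"raw"`` (default): subtract from raw fluorescence before binning
        and ΔF/F0.  ``"dff"``: subtract from the ΔF/F0 traces (background
        then expressed in ΔF/F0 units).
    """

    bin_ms: float = 200.0
    baseline_method: str = "global_median"
    baseline_percentile: float = 10.0
    background: Union[float, np.ndarray] = 0.0
    background_stage: str = "raw"

    def __post_init__(self) -> None:
        if not self.bin_ms > 0:
            raise ValueError("bin_ms must be positive")
        if self.baseline_method not in ("global_percentile", "global_median"):
            raise ValueError(
                "baseline_method must be 'global_percentile' or "
                f"'global_median', got {self.baseline_method!r}"
            )
        if not 0 < self.baseline_percentile < 100:
            raise ValueError("baseline_percentile must be in (0, 100)")
        if self.background_stage not in ("raw", "dff"):
            raise ValueError("background_stage must be 'raw' or 'dff'")


def _binning_factor(sampling_rate: float, bin_ms: float) -> int:
    """Integer number of source frames per bin, or raise."""
    frame_ms = 1000.0 / sampling_rate
    k = bin_ms / frame_ms
    k_int = int(round(k))
    if k_int < 1 or abs(k - k_int) > 1e-9 * max(1.0, k):
        raise ValueError(
            f"bin width {bin_ms} ms is not an integer multiple of the "
            f"frame period {frame_ms:g} ms (sampling rate {sampling_rate:g} Hz)"
        )
    return k_int


def bin_time_average(trace_matrix: TraceMatrix, bin_ms: float) -> TraceMatrix:
    """Average consecutive frames into non-overlapping bins of ``bin_ms``.

    Each output frame is the arithmetic mean of ``k`` consecutive input
    frames, where ``k = bin_ms / frame_period``; trailing frames that do
    not fill a complete bin are dropped.  The output sampling rate is the
    input rate divided by ``k``; ``k == 1`` returns an identical matrix.
    """
    k = _binning_factor(trace_matrix.sampling_rate, bin_ms)
    if k == 1:
        return dataclasses.replace(trace_matrix)
    n_bins = trace_matrix.n_frames // k
    if n_bins < 2:
        raise ValueError(
            f"binning by {k} leaves {n_bins} frame(s); need at least 2"
        )
    vals = trace_matrix.values[:, : n_bins * k]
    binned = vals.reshape(trace_matrix.n_rois, n_bins, k).mean(axis=2)
    return dataclasses.replace(
        trace_matrix,
        values=binned,
        sampling_rate=trace_matrix.sampling_rate / k,
    )


def subtract_background(
    trace_matrix: TraceMatrix, background: Union[float, np.ndarray, Sequence[float]]
) -> TraceMatrix:
    """Subtract a scalar or per-frame background from every ROI trace."""
    bg = np.asarray(background, dtype=np.float64)
    if bg.ndim == 0:
        corrected = trace_matrix.values - float(bg)
    elif bg.ndim == 1:
        if bg.shape[0] != trace_matrix.n_frames:
            raise ValueError(
                f"per-frame background has {bg.shape[0]} samples but the "
                f"recording has {trace_matrix.n_frames} frames"
            )
        corrected = trace_matrix.values - bg[np.newaxis, :]
    else:
        raise ValueError("background must be a scalar or a 1-D per-frame trace")
    return dataclasses.replace(trace_matrix, values=corrected)


def _baseline_f0(values: np.ndarray, params: PreprocessParams) -> np.ndarray:
    if params.baseline_method == "global_median":
        return np.median(values, axis=1)
    return np.percentile(values, params.baseline_percentile, axis=1)


def compute_dff(
    trace_matrix: TraceMatrix, params: PreprocessParams | None = None
) -> DffMatrix:
    """Normalise each ROI trace to ΔF/F0 = (F − F0) / F0.

    F0 is a global statistic of the ROI's own trace (median by default, or
    a low percentile), which is robust when transients are sparse.  A
    non-positive F0 indicates un-offset or over-corrected data and is
    rejected with the offending ROI named.
    """
    params = params or PreprocessParams()
    f0 = _baseline_f0(trace_matrix.values, params)
    bad = np.nonzero(f0 <= 0)[0]
    if bad.size:
        roi = trace_matrix.roi_ids[bad[0]]
        raise ValueError(
            f"baseline F0 is not positive for ROI {roi!r} "
            f"(F0 = {f0[bad[0]]:g}); check offsets and background correction"
        )
    dff = (trace_matrix.values - f0[:, None]) / f0[:, None]
    return DffMatrix(
        values=dff,
        sampling_rate=trace_matrix.sampling_rate,
        roi_ids=trace_matrix.roi_ids,
        session=trace_matrix.session,
        meta={
            "baseline_method": params.baseline_method,
            "baseline_percentile": params.baseline_percentile,
            "f0": f0,
        },
    )


def preprocess(
    trace_matrix: TraceMatrix, params: PreprocessParams | None = None
) -> DffMatrix:
    """Full preprocessing chain: bin, subtract background, normalise.

    Background is subtracted from the raw fluorescence before binning when
    ``background_stage == "raw"`` (the default), or from the ΔF/F0 traces
    afterwards when ``"dff"``.
    """
    params = params or PreprocessParams()
    tm = trace_matrix
    if params.background_stage == "raw":
        tm = subtract_background(tm, params.background)
    binned = bin_time_average(tm, params.bin_ms)
    dff = compute_dff(binned, params)
    if params.background_stage == "dff":
        sub = subtract_background(dff, params.background)
        dff = DffMatrix(
            values=sub.values,
            sampling_rate=dff.sampling_rate,
            roi_ids=dff.roi_ids,
            session=dff.session,
            meta=dff.meta,
        )
    dff.meta["bin_ms"] = params.bin_ms
    dff.meta["background_stage"] = params.background_stage
    return dff
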