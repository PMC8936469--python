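"""Synthetic one-photon calcium recordings with known ground truth.

The generator emulates 10-minute, 10 fps GCaMP6s recordings of a few tens
of striatal ROIs: sparse Poisson transients with a double-exponential
kernel, partial population synchrony via a thinned shared event schedule,
white Gaussian photometric noise, and a slow sinusoidal baseline drift.
Every draw is fully determined by an integer seed, and the true event
times, amplitudes, and shared-event assignments are returned alongside
the raw fluorescence so that detection and metric recovery can be tested
end to end without any recorded data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trace_model import SessionInfo, TraceMatrix

__all__ = [
    "KernelParams",
    "PopulationSimParams",
    "TrueEvent",
    "SyntheticGroundTruth",
    "PhaseEffect",
    "DaySpec",
    "make_kernel",
    "simulate_roi_trace",
    "simulate_population",
    "make_phase_schedule",
]


@dataclass(frozen=True)
class KernelParams:
    """Shape of the simulated transient: k(t) = e^(−t/τ_decay) − e^(−t/τ_rise).

    Defaults (0.2 s rise, 1.0 s decay) approximate GCaMP6s kinetics.
    With ``peak_normalized`` the discrete kernel is scaled to a maximum
    of exactly 1, so an event's amplitude parameter equals its peak
    ΔF/F0 contribution.
    """

    rise_tau_s: float = 0.2
    decay_tau_s: float = 1.0
    peak_normalized: bool = True

    def __post_init__(self) -> None:
        if not self.rise_tau_s > 0:
            raise ValueError("rise_tau_s must be positive")
        if not self.decay_tau_s > self.rise_tau_s:
            raise ValueError("decay_tau_s must exceed rise_tau_s")


@dataclass(frozen=True)
class PopulationSimParams:
    """Population simulation settings.

    Each ROI receives a private Poisson event stream of rate
    ``event_rate_per_min × (1 − sync_prob)`` plus each event of a shared
    population schedule (rate ``shared_rate_per_min``, defaulting to
    ``event_rate_per_min``) independently with probability ``sync_prob``,
    so the expected per-ROI rate stays at ``event_rate_per_min`` while
    ``sync_prob`` moves events between private and population-wide.
    Amplitudes are drawn per event from a normal truncated to positive
    values.  ``noise_sd`` is the white-noise SD in ΔF/F0 units at the raw
    frame rate; ``drift_amplitude`` is the peak of a slow sinusoidal
    baseline wander in fluorescence units.
    """

    n_rois: int = 30
    duration_s: float = 600.0
    sampling_rate: float = 10.0
    event_rate_per_min: float = 1.0
    sync_prob: float = 0.5
    shared_rate_per_min: float | None = None
    amplitude_mean: float = 0.25
    amplitude_sd: float = 0.05
    noise_sd: float = 0.05
    f0_mean: float = 100.0
    f0_sd: float = 10.0
    drift_amplitude: float = 2.0
    drift_period_s: float = 120.0
    kernel: KernelParams = field(default_factory=KernelParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ValueError("n_rois must be at least 1")
        if not self.duration_s > 0 or not self.sampling_rate > 0:
            raise ValueError("duration_s and sampling_rate must be positive")
        if self.event_rate_per_min < 0:
            raise ValueError("event_rate_per_min must be non-negative")
        if self.shared_rate_per_min is not None and self.shared_rate_per_min < 0:
            raise ValueError("shared_rate_per_min must be non-negative")
        if not 0.0 <= self.sync_prob <= 1.0:
            raise ValueError("sync_prob must lie in [0, 1]")
        if not self.amplitude_mean > 0:
            raise ValueError("amplitude_mean must be positive")
        if self.amplitude_sd < 0 or self.noise_sd < 0:
            raise ValueError("amplitude_sd and noise_sd must be non-negative")
        if not self.f0_mean > 0:
            raise ValueError("f0_mean must be positive")
        if self.f0_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("f0_sd and drift_amplitude must be non-negative")
        if not self.drift_period_s > 0:
            raise ValueError("drift_period_s must be positive")

    @property
    def effective_shared_rate_per_min(self) -> float:
        if self.shared_rate_per_min is None:
            return self.event_rate_per_min
        return self.shared_rate_per_min


@dataclass(frozen=True)
class TrueEvent:
    """One ground-truth transient; ``shared_id`` links population events."""

    time_s: float
    amplitude: float
    shared_id: int | None = None


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Everything needed to score a detection run against the simulation."""

    roi_events: dict[str, tuple[TrueEvent, ...]]
    shared_times: tuple[float, ...]
    params: PopulationSimParams
    session: SessionInfo | None = None

    def event_count(self, roi_id: str) -> int:
        return len(self.roi_events[roi_id])

    def to_json_dict(self) -> dict:
        return {
            "shared_times": list(self.shared_times),
            "roi_events": {
                roi: [dataclasses.asdict(e) for e in evs]
                for roi, evs in self.roi_events.items()
            },
            "params": _params_to_dict(self.params),
            "session": (
                None if self.session is None else dataclasses.asdict(self.session)
            ),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


def _params_to_dict(params: PopulationSimParams) -> dict:
    d = dataclasses.asdict(params)
    d["kernel"] = dataclasses.asdict(params.kernel)
    return d


def make_kernel(
    params: KernelParams | None = None, sampling_rate: float = 10.0
) -> np.ndarray:
    """Sample the double-exponential transient at the frame period.

    The kernel starts at 0, rises with τ_rise, decays with τ_decay, and is
    truncated once it falls below 0.1% of its maximum; with
    ``peak_normalized`` its (discrete) maximum is exactly 1.
    """
    params = params or KernelParams()
    if not sampling_rate > 0:
        raise ValueError("sampling_rate must be positive")
    tr, td = params.rise_tau_s, params.decay_tau_s
    dt = 1.0 / sampling_rate
    # continuous peak, then extend until the decay tail is below cutoff
    t_peak = np.log(td / tr) * tr * td / (td - tr)
    k_peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    cutoff = 1e-3 * k_peak
    t_end = t_peak + td * np.log(1.0 / 1e-3)
    while np.exp(-t_end / td) - np.exp(-t_end / tr) >= cutoff:
        t_end += td
    t = np.arange(0.0, t_end + dt, dt)
    k = np.exp(-t / td) - np.exp(-t / tr)
    keep = np.flatnonzero(k >= cutoff)
    if keep.size:
        k = k[: keep[-1] + 1]
    else:  # pathological sampling coarser than the transient
        k = np.array([k_peak])
    if params.peak_normalized:
        k = k / k.max()
    return k


def simulate_roi_trace(
    event_times: Sequence[float],
    amplitudes: Sequence[float],
    kernel: np.ndarray,
    *,
    noise_sd: float,
    f0: float,
    drift_amplitude: float,
    duration_s: float,
    sampling_rate: float,
    rng: np.random.Generator | int,
    drift_period_s: float = 120.0,
    drift_phase: float = 0.0,
) -> np.ndarray:
    """Assemble one raw fluorescence trace from ground-truth events.

    The ΔF/F0 signal is the sum of amplitude-scaled kernels placed at the
    event onsets, plus white Gaussian noise and a slow sinusoid of peak
    ``drift_amplitude`` (fluorescence units); the raw trace is
    ``F = f0 × (1 + signal)``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if not f0 > 0:
        raise ValueError("f0 must be positive")
    n = int(round(duration_s * sampling_rate))
    times = np.asarray(event_times, dtype=np.float64)
    amps = np.asarray(amplitudes, dtype=np.float64)
    if times.shape != amps.shape:
        raise ValueError("event_times and amplitudes must align")
    if times.size and (times.min() < 0 or times.max() >= duration_s):
        raise ValueError("event times must lie in [0, duration_s)")
    signal = np.zeros(n)
    for t0, a in zip(times, amps):
        i = int(np.floor(t0 * sampling_rate))
        seg = kernel[: max(0, n - i)]
        signal[i : i + seg.size] += a * seg
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, n)
    if drift_amplitude > 0:
        tgrid = np.arange(n) / sampling_rate
        signal = signal + (drift_amplitude / f0) * np.sin(
            2.0 * np.pi * tgrid / drift_period_s + drift_phase
        )
    return f0 * (1.0 + signal)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal draws truncated to strictly positive values (by rejection)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def simulate_population(
    params: PopulationSimParams | None = None,
    session: SessionInfo | None = None,
) -> tuple[TraceMatrix, SyntheticGroundTruth]:
    """Simulate a whole ROI population for one session.

    The shared schedule is a Poisson process; each ROI joins each shared
    event with probability ``sync_prob`` and adds its own private Poisson
    stream, so ``sync_prob = 1`` (with the default matched shared rate)
    makes all ROIs fire at identical times while ``sync_prob = 0``
    decouples them completely.  Fully deterministic given ``params.seed``.
    """
    params = params or PopulationSimParams()
    rng = np.random.default_rng(params.seed)
    T = params.duration_s
    shared_rate = params.effective_shared_rate_per_min / 60.0
    n_shared = rng.poisson(shared_rate * T)
    shared_times = np.sort(rng.uniform(0.0, T, n_shared))
    kernel = make_kernel(params.kernel, params.sampling_rate)
    private_rate = params.event_rate_per_min * (1.0 - params.sync_prob) / 60.0

    if session is None:
        session = SessionInfo(duration_s=T)
    roi_ids = tuple(f"roi{i:03d}" for i in range(params.n_rois))
    traces = np.empty((params.n_rois, int(round(T * params.sampling_rate))))
    roi_events: dict[str, tuple[TrueEvent, ...]] = {}
    for i, roi in enumerate(roi_ids):
        f0 = max(rng.normal(params.f0_mean, params.f0_sd), 0.1 * params.f0_mean)
        n_priv = rng.poisson(private_rate * T)
        priv_times = rng.uniform(0.0, T, n_priv)
        joined = (
            rng.random(n_shared) < params.sync_prob
            if n_shared
            else np.zeros(0, dtype=bool)
        )
        events = [(float(t), None) for t in priv_times] + [
            (float(shared_times[j]), int(j)) for j in np.flatnonzero(joined)
        ]
        events.sort(key=lambda e: e[0])
        amps = _truncated_normal(
            rng, params.amplitude_mean, params.amplitude_sd, len(events)
        )
        drift_phase = rng.uniform(0.0, 2.0 * np.pi)
        traces[i] = simulate_roi_trace(
            [t for t, _ in events],
            amps,
            kernel,
            noise_sd=params.noise_sd,
            f0=f0,
            drift_amplitude=params.drift_amplitude,
            duration_s=T,
            sampling_rate=params.sampling_rate,
            rng=rng,
            drift_period_s=params.drift_period_s,
            drift_phase=drift_phase,
        )
        roi_events[roi] = tuple(
            TrueEvent(time_s=float(t), amplitude=float(a), shared_id=sid)
            for (t, sid), a in zip(events, amps)
        )
    trace_matrix = TraceMatrix(
        values=traces,
        sampling_rate=params.sampling_rate,
        roi_ids=roi_ids,
        session=session,
    )
    truth = SyntheticGroundTruth(
        roi_events=roi_events,
        shared_times=tuple(float(t) for t in shared_times),
        params=params,
        session=session,
    )
    return trace_matrix, truth


@dataclass(frozen=True)
class PhaseEffect:
    """Per-phase multipliers on event rate and synchrony probability.

    Baseline days always use the nominal parameters; stimulation and
    post-stimulation days scale the event rate (both private and shared)
    and the synchrony probability (clamped to [0, 1]).  Amplitude
    parameters are never touched: the manipulation modelled here changes
    how often and how coherently cells fire, not how large their
    transients are.
    """

    stim_frequency_mult: float = 1.0
    stim_sync_mult: float = 1.0
    post_frequency_mult: float = 1.0
    post_sync_mult: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "stim_frequency_mult",
            "stim_sync_mult",
            "post_frequency_mult",
            "post_sync_mult",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def multipliers(self, phase: str) -> tuple[float, float]:
        if phase == "stimulation":
            return self.stim_frequency_mult, self.stim_sync_mult
        if phase == "poststimulation":
            return self.post_frequency_mult, self.post_sync_mult
        return 1.0, 1.0


@dataclass(frozen=True)
class DaySpec:
    """Simulation parameters for one imaging day of the timeline."""

    day: int
    phase: str
    params: PopulationSimParams


def make_phase_schedule(
    base_params: PopulationSimParams | None = None,
    effect: PhaseEffect | None = None,
    baseline_days: int = 2,
    stim_days: int = 4,
    post_days: int = 5,
    day_spacing: int = 2,
    first_day: int = 1,
) -> list[DaySpec]:
    """Imaging-day schedule across baseline → stimulation → post phases.

    Days are spaced ``day_spacing`` apart (imaging every second day by
    default); the default counts model 2 baseline days, a 7-day
    stimulation block imaged 4 times, and 10 post-stimulation days imaged
    5 times.
    """
    base_params = base_params or PopulationSimParams()
    effect = effect or PhaseEffect()
    if baseline_days < 0 or stim_days < 0 or post_days < 0:
        raise ValueError("day counts must be non-negative")
    if day_spacing < 1:
        raise ValueError("day_spacing must be at least 1")
    phases = (
        ["baseline"] * baseline_days
        + ["stimulation"] * stim_days
        + ["poststimulation"] * post_days
    )
    schedule = []
    for idx, phase in enumerate(phases):
        fmult, smult = effect.multipliers(phase)
        params = dataclasses.replace(
            base_params,
            event_rate_per_min=base_params.event_rate_per_min * fmult,
            shared_rate_per_min=base_params.effective_shared_rate_per_min * fmult,
            sync_prob=min(1.0, base_params.sync_prob * smult),
        )
        schedule.append(
            DaySpec(day=first_day + idx * day_spacing, phase=phase, params=params)
        )
    return schedule
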