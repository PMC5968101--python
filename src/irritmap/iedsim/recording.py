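"""Scalp-EEG simulator: IED events from cortical dipoles plus colored noise.

Events are scheduled on an interleaved slot lattice: the recording is divided
into slots of ``min_gap_s``; each subtype draws its event slots, with an
independent seeded stream, from its own congruence class of slot indices.
This guarantees (a) no two events fall closer than the minimum gap and (b)
each subtype's event times depend only on its own phase and stream, so
simulating subtypes separately and summing the clean signals reproduces the
joint simulation exactly.

Noise is a per-channel mixture of white Gaussian and a unit-variance AR(1)
process (low-frequency-dominated, a pragmatic stand-in for the 1/f-like EEG
background), scaled post hoc so that the mean event peak over the background
standard deviation on the best channel matches the requested SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from ..errors import ConfigError
from ..headmodel.leadfield import LeadField
from ..recording import Recording
from .templates import IEDTemplate

__all__ = [
    "NoiseSpec",
    "SubtypeSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_recording",
]


@dataclass
class NoiseSpec:
    """Background noise model: white + AR(1) mixture.

    ``sd`` is the per-channel standard deviation in microvolts before any
    SNR calibration; ``pink_fraction`` is the variance share of the colored
    component; ``ar_coeff`` its lag-one autocorrelation.
    """

    sd: float = 1.0
    pink_fraction: float = 0.5
    ar_coeff: float = 0.9

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError("noise sd must be non-negative")
        if not 0 <= self.pink_fraction <= 1:
            raise ConfigError("pink_fraction must lie in [0, 1]")
        if not -1 < self.ar_coeff < 1:
            raise ConfigError("ar_coeff must lie in (-1, 1)")


@dataclass
class SubtypeSpec:
    """One simulated IED subtype: waveform, generator, event count.

    ``source_index`` addresses a column block of the lead field;
    ``moment`` is the dipole moment in nA*m (3-vector for free-orientation
    lead fields, scalar for fixed).  ``phase`` fixes the subtype's slot
    congruence class; it defaults to the subtype's position in the config.
    """

    template: IEDTemplate
    source_index: int
    n_events: int
    moment: np.ndarray | float = 1.0
    parcel_id: int | None = None
    phase: int | None = None


@dataclass
class SimulationConfig:
    n_channels: int
    sampling_rate: float
    duration_s: float
    subtypes: list[SubtypeSpec]
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    snr: float | None = 5.0
    min_gap_s: float = 0.5
    edge_margin_s: float = 0.5
    jitter_s: float = 0.1
    n_phases: int | None = None
    equalize_subtype_peaks: bool = True
    peak_uv: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr is not None and self.snr <= 0:
            raise ConfigError("snr must be positive")
        if not self.subtypes:
            raise ConfigError("at least one subtype required")
        if self.min_gap_s <= 0:
            raise ConfigError("min_gap_s must be positive")
        if self.jitter_s * 2 >= self.min_gap_s:
            raise ConfigError("jitter must be smaller than half the slot gap")


@dataclass
class GroundTruth:
    """Per-event and per-subtype truth for a simulated recording."""

    peak_samples: np.ndarray      # per-event peak sample index
    labels: np.ndarray            # per-event subtype label (0..K-1)
    source_indices: np.ndarray    # per-event lead-field source index
    parcel_ids: list[int | None]  # per-subtype parcel
    waveforms: list[np.ndarray]   # per-subtype unit-peak template
    kinds: list[str]              # per-subtype {"spike", "sharp_wave"}

    @property
    def n_events(self) -> int:
        return self.peak_samples.size

    def events_of(self, label: int) -> np.ndarray:
        return self.peak_samples[self.labels == label]


def _event_times(cfg: SimulationConfig) -> list[np.ndarray]:
    """Slot-lattice event peak times (s) per subtype."""
    n_phases = cfg.n_phases or len(cfg.subtypes)
    t0 = cfg.edge_margin_s
    t1 = cfg.duration_s - cfg.edge_margin_s
    n_slots = int(np.floor((t1 - t0) / cfg.min_gap_s))
    times = []
    for k, sub in enumerate(cfg.subtypes):
        phase = sub.phase if sub.phase is not None else k
        slots = np.arange(phase, n_slots, n_phases)
        if sub.n_events > slots.size:
            raise ConfigError(
                f"subtype {k}: {sub.n_events} events do not fit in "
                f"{slots.size} available slots; increase duration_s"
            )
        rng = np.random.default_rng([cfg.seed, 1000 + phase])
        chosen = np.sort(rng.choice(slots, size=sub.n_events, replace=False))
        jitter = rng.uniform(-cfg.jitter_s, cfg.jitter_s, size=sub.n_events)
        times.append(t0 + (chosen + 0.5) * cfg.min_gap_s + jitter)
    return times


def simulate_recording(
    cfg: SimulationConfig, lf: LeadField
) -> tuple[Recording, GroundTruth]:
    """Simulate a scalp recording and its ground truth.

    The clean signal is the sum over events of (template x lead-field
    column); noise is added afterwards, scaled to the configured SNR (or
    used at its nominal sd when ``cfg.snr`` is None).
    """
    if lf.n_electrodes != cfg.n_channels:
        raise ConfigError("lead field electrode count does not match config")
    for k, sub in enumerate(cfg.subtypes):
        if not 0 <= sub.source_index < lf.n_sources:
            raise ConfigError(f"subtype {k}: source index out of lead-field range")

    fs = cfg.sampling_rate
    n_samples = int(round(cfg.duration_s * fs))
    clean = np.zeros((cfg.n_channels, n_samples))

    times = _event_times(cfg)
    peaks, labels, src_idx = [], [], []
    topographies = []
    for k, sub in enumerate(cfg.subtypes):
        g = lf.source_gain(sub.source_index)
        if g.ndim == 2:
            moment = np.asarray(sub.moment, dtype=float).reshape(3)
            topo = g @ moment
        else:
            topo = g * float(np.atleast_1d(sub.moment)[0])
        if cfg.equalize_subtype_peaks:
            # every subtype reaches the same best-channel peak, so the
            # configured SNR applies to each subtype, not just their mean
            topo = topo * (cfg.peak_uv / np.abs(topo).max())
        topographies.append(topo)
        wave = sub.template.waveform
        pk = sub.template.peak_index
        for t in times[k]:
            peak = int(round(t * fs))
            start = peak - pk
            stop = start + wave.size
            if start < 0 or stop > n_samples:
                raise ConfigError("event template does not fit inside recording")
            clean[:, start:stop] += np.outer(topo, wave)
            peaks.append(peak)
            labels.append(k)
            src_idx.append(sub.source_index)

    order = np.argsort(peaks)
    truth = GroundTruth(
        peak_samples=np.asarray(peaks)[order],
        labels=np.asarray(labels)[order],
        source_indices=np.asarray(src_idx)[order],
        parcel_ids=[s.parcel_id for s in cfg.subtypes],
        waveforms=[s.template.waveform.copy() for s in cfg.subtypes],
        kinds=[s.template.kind for s in cfg.subtypes],
    )

    noise = _make_noise(cfg, n_samples)
    if noise is not None and cfg.snr is not None:
        # mean event peak across events, on each event's best channel
        peak_amps = [
            np.abs(topographies[lbl]).max()
            for lbl in truth.labels
        ]
        target_sd = float(np.mean(peak_amps)) / cfg.snr
        noise *= target_sd  # noise is unit-variance per channel here
    elif noise is not None:
        noise *= cfg.noise.sd
    data = clean if noise is None else clean + noise

    rec = Recording(data=data, sampling_rate=fs, referenced=False)
    return rec, truth


def _make_noise(cfg: SimulationConfig, n_samples: int) -> np.ndarray | None:
    """Unit-variance per-channel noise mixture, or None when sd == 0."""
    if cfg.noise.sd == 0 and cfg.snr is None:
        return None
    if cfg.noise.sd == 0:
        return None
    rng = np.random.default_rng([cfg.seed, 7])
    white = rng.standard_normal((cfg.n_channels, n_samples))
    pf = cfg.noise.pink_fraction
    if pf == 0:
        return white
    phi = cfg.noise.ar_coeff
    innov = rng.standard_normal((cfg.n_channels, n_samples))
    colored = scipy.signal.lfilter([1.0], [1.0, -phi], innov, axis=1)
    colored *= np.sqrt(1.0 - phi * phi)  # unit stationary variance
    return np.sqrt(1.0 - pf) * white + np.sqrt(pf) * colored
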