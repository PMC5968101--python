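"""Epoch extraction: assemble the electrodes x time x samples IED tensor."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..errors import EpochError
from ..recording import Recording
from .detect import EventList

__all__ = ["IEDTensor", "extract_epochs"]

logger = logging.getLogger(__name__)


@dataclass
class IEDTensor:
    """Electrodes x time x samples array of IED epochs.

    Each sample (third axis) is one detected event, centered on its peak,
    baseline-corrected by the mean of the first fifth of the window.
    ``events`` holds the retained events in sample order.
    """

    values: np.ndarray
    window_ms: float
    sampling_rate: float
    events: EventList

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise EpochError("tensor must be electrodes x time x samples")
        if self.values.shape[2] != len(self.events):
            raise EpochError("sample dimension must match retained events")

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[2]

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            values=self.values,
            window_ms=self.window_ms,
            sampling_rate=self.sampling_rate,
            peak_samples=self.events.peak_samples,
            durations_ms=self.events.durations_ms,
            kinds=np.array(self.events.kinds),
        )


def extract_epochs(
    rec: Recording, events: EventList, window_ms: float = 300.0
) -> IEDTensor:
    """Cut peak-centered epochs and stack them into an IED tensor.

    Events whose window does not fit inside the recording are dropped (and
    logged).  The per-channel baseline — the mean over the first 20% of the
    window — is subtracted from each epoch.
    """
    fs = rec.sampling_rate
    half = int(round(window_ms / 1000.0 * fs / 2.0))
    n_win = 2 * half
    if n_win > rec.n_samples:
        raise EpochError("epoch window longer than the recording")
    n_base = max(1, int(round(0.2 * n_win)))

    kept, epochs = [], []
    for e in events:
        start = e.peak_sample - half
        stop = e.peak_sample + half
        if start < 0 or stop > rec.n_samples:
            logger.info("event at sample %d dropped: window out of bounds", e.peak_sample)
            continue
        epoch = rec.data[:, start:stop].copy()
        epoch -= epoch[:, :n_base].mean(axis=1, keepdims=True)
        epochs.append(epoch)
        kept.append(e)
    values = (
        np.stack(epochs, axis=2) if epochs else np.empty((rec.n_channels, n_win, 0))
    )
    return IEDTensor(
        values=values,
        window_ms=window_ms,
        sampling_rate=fs,
        events=EventList(events=kept, sampling_rate=fs),
    )
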