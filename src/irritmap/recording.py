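"""Multichannel scalp-EEG container with plain-text I/O.

A :class:`Recording` holds a channels x samples potential matrix in microvolts
together with its sampling rate, channel names, and referencing state.  On-disk
format is a whitespace-delimited matrix (one row per channel) plus a JSON
sidecar carrying the metadata, so recordings round-trip without any binary
dependency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError

__all__ = ["Recording"]


@dataclass
class Recording:
    """Channels x samples scalp potentials (microvolts).

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Potentials in microvolts.
    sampling_rate : float
        Sampling frequency in Hz; must be positive.
    channel_names : list of str, optional
        Defaults to ``Ch01..ChNN``.
    referenced : bool
        True once the average reference has been applied.
    band : tuple of float, optional
        (low, high) Hz of the last band-pass applied, if any.
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)
    referenced: bool = False
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigError("recording data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ConfigError("recording contains non-finite values")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"Ch{i + 1:02d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ConfigError("channel_names length does not match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path) -> None:
        """Write ``<path>`` (delimited matrix) and ``<path>.json`` (metadata)."""
        path = Path(path)
        np.savetxt(path, self.data, fmt="%.6f")
        meta = {
            "sampling_rate": self.sampling_rate,
            "channel_names": self.channel_names,
            "referenced": self.referenced,
            "band": list(self.band) if self.band else None,
            "units": "uV",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Recording":
        path = Path(path)
        data = np.loadtxt(path, ndmin=2)
        meta_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(meta_path.read_text())
        band = tuple(meta["band"]) if meta.get("band") else None
        return cls(
            data=data,
            sampling_rate=meta["sampling_rate"],
            channel_names=meta.get("channel_names", []),
            referenced=meta.get("referenced", False),
            band=band,
        )
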