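"""Lead-field container: linear map from dipole moments to scalp potentials."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..errors import ConfigError

__all__ = ["LeadField"]


@dataclass
class LeadField:
    """Gain matrix in microvolts per nA*m.

    ``gain`` is electrodes x (sources * 3) for free-orientation sources (the
    three columns per source are the x/y/z unit-moment responses) or
    electrodes x sources when the source space carries fixed orientations.
    """

    gain: np.ndarray
    n_sources: int
    orientation: str = "free"  # "free" | "fixed"
    referenced: bool = False

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise ConfigError("gain must be 2-D")
        if not np.all(np.isfinite(self.gain)):
            raise ConfigError("gain contains non-finite entries")
        expected = self.n_sources * (3 if self.orientation == "free" else 1)
        if self.gain.shape[1] != expected:
            raise ConfigError(
                f"gain has {self.gain.shape[1]} columns, expected {expected}"
            )
        if self.referenced:
            col_sums = self.gain.sum(axis=0)
            scale = max(np.abs(self.gain).max(), 1.0)
            if np.abs(col_sums).max() > 1e-9 * scale:
                raise ConfigError("referenced lead field columns must sum to zero")

    @property
    def n_electrodes(self) -> int:
        return self.gain.shape[0]

    def source_gain(self, index: int) -> np.ndarray:
        """Gain block of one source: (n_electrodes, 3) or (n_electrodes,)."""
        if self.orientation == "free":
            return self.gain[:, 3 * index : 3 * index + 3]
        return self.gain[:, index]

    def fix_orientation(self, orientations: np.ndarray) -> "LeadField":
        """Collapse a free-orientation gain onto per-source unit orientations."""
        if self.orientation != "free":
            raise ConfigError("lead field already has fixed orientations")
        ori = np.asarray(orientations, dtype=float)
        if ori.shape != (self.n_sources, 3):
            raise ConfigError("orientations must be (n_sources, 3)")
        g = self.gain.reshape(self.n_electrodes, self.n_sources, 3)
        fixed = np.einsum("esk,sk->es", g, ori)
        return LeadField(fixed, self.n_sources, "fixed", self.referenced)

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path) -> None:
        """Write ``<path>.npy`` (gain) and ``<path>.json`` (shape metadata)."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.gain)
        meta = {
            "n_sources": self.n_sources,
            "orientation": self.orientation,
            "referenced": self.referenced,
            "units": "uV per nA*m",
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LeadField":
        path = Path(path)
        gain = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            gain,
            n_sources=meta["n_sources"],
            orientation=meta["orientation"],
            referenced=meta["referenced"],
        )
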