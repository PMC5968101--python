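"""Electrode montages and discretized cortical source spaces."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..errors import ConfigError

__all__ = ["Montage", "SourceSpace"]


@dataclass
class Montage:
    """Named electrode positions (mm).

    The on-disk format is a whitespace-delimited ``label x y z`` file, one
    electrode per line.
    """

    names: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape != (len(self.names), 3):
            raise ConfigError("montage positions must be (n_electrodes, 3)")
        if len(set(self.names)) != len(self.names):
            raise ConfigError("electrode labels must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def save(self, path: str | Path) -> None:
        lines = [
            f"{name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}"
            for name, p in zip(self.names, self.positions)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Montage":
        names, rows = [], []
        for line in Path(path).read_text().splitlines():
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
        return cls(names=names, positions=np.array(rows))


@dataclass
class SourceSpace:
    """Dipole source positions (mm) with optional fixed orientations.

    ``parcel_ids`` assigns each source to a cortical parcel; ids follow the
    Paxinos-Watson convention used throughout the package (right hemisphere
    1-48, left hemisphere 49-96, left = right + 48).
    """

    positions: np.ndarray
    orientations: np.ndarray | None = None
    parcel_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[1] != 3:
            raise ConfigError("source positions must be (n_sources, 3)")
        if self.orientations is not None:
            self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
            if self.orientations.shape != self.positions.shape:
                raise ConfigError("orientations must match positions")
            norms = np.linalg.norm(self.orientations, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise ConfigError("orientations must be unit-norm")
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=int)
        if self.parcel_ids.size and self.parcel_ids.size != self.n_sources:
            raise ConfigError("parcel_ids must have one entry per source")

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    @property
    def fixed_orientation(self) -> bool:
        return self.orientations is not None
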