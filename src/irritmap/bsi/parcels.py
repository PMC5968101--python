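"""Cortical parcellation lookup, Paxinos-Watson convention for Wistar rats.

Region identifiers follow the standard numbering used with the Wistar-rat
probabilistic atlas: each cortical structure has a right-hemisphere id in
1-48 and a left-hemisphere id in 49-96, with left = right + 48; e.g. M1 is
19 (right) / 67 (left) and S1BF is 31 (right) / 79 (left).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import ConfigError, LookupError_

__all__ = ["Parcellation", "parcel_label", "default_parcellation", "REGIONS"]

# region name -> right-hemisphere id (left id = right + 48)
REGIONS = {
    "AID": 1, "AIP": 2, "AIV": 3, "Apir": 4, "Au1": 5, "AuD": 6, "AuV": 7,
    "Cg1": 8, "Cg2": 9, "DI": 10, "DIEnt": 11, "DLEnt": 12, "DLO": 13,
    "Ect": 14, "Fr3": 15, "GI": 16, "GIDI": 17, "LPtA": 18, "M1": 19,
    "M2": 20, "MEnt": 21, "MPtA": 22, "PRh": 23, "PtPC": 24, "PtPD": 25,
    "PtPR": 26, "RSD": 27, "RSGb": 28, "RSGc": 29, "S1": 30, "S1BF": 31,
    "S1DZ": 32, "S1DZ0": 33, "S1FL": 34, "S1HL": 35, "S1J": 36, "S1Sh": 37,
    "S1Tr": 38, "S1ULp": 39, "S2": 40, "TeA": 41, "V1": 42, "V1B": 43,
    "V1M": 44, "V2L": 45, "V2ML": 46, "V2MM": 47, "VIEnt": 48,
}

_N_REGIONS = 48


@dataclass
class Parcellation:
    """id -> (name, hemisphere) lookup plus source-to-parcel mapping.

    ``source_parcels`` maps each source-space dipole to its parcel id;
    contralateral pairing is id <-> id +/- 48.
    """

    table: dict[int, tuple[str, str]]
    source_parcels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.source_parcels = np.asarray(self.source_parcels, dtype=int)
        for pid in self.table:
            if self.contralateral(pid) not in self.table:
                raise ConfigError(f"parcel {pid} has no contralateral partner")

    @staticmethod
    def contralateral(parcel_id: int) -> int:
        """The mirrored parcel id (right 1-48 <-> left 49-96)."""
        if 1 <= parcel_id <= _N_REGIONS:
            return parcel_id + _N_REGIONS
        if _N_REGIONS < parcel_id <= 2 * _N_REGIONS:
            return parcel_id - _N_REGIONS
        raise LookupError_(f"parcel id {parcel_id} outside 1-96")

    def label(self, parcel_id: int) -> tuple[str, str]:
        if parcel_id not in self.table:
            raise LookupError_(f"unknown parcel id {parcel_id}")
        return self.table[parcel_id]

    def sources_in(self, parcel_id: int) -> np.ndarray:
        return np.flatnonzero(self.source_parcels == parcel_id)

    def save(self, path: str | Path) -> None:
        rows = [
            {"id": pid, "name": name, "hemisphere": hemi}
            for pid, (name, hemi) in sorted(self.table.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path, source_parcels=None) -> "Parcellation":
        df = pd.read_csv(path)
        table = {
            int(r["id"]): (str(r["name"]), str(r["hemisphere"]))
            for _, r in df.iterrows()
        }
        return cls(table, source_parcels if source_parcels is not None else [])


def default_parcellation(source_parcels=None) -> Parcellation:
    """The full 96-id cortical lookup (right 1-48, left 49-96)."""
    table: dict[int, tuple[str, str]] = {}
    for name, rid in REGIONS.items():
        table[rid] = (name, "right")
        table[rid + _N_REGIONS] = (name, "left")
    return Parcellation(table, source_parcels if source_parcels is not None else [])


def parcel_label(parcel_id: int, parcellation: Parcellation | None = None) -> tuple[str, str]:
    """(region name, hemisphere) of a parcel id."""
    parcellation = parcellation or default_parcellation()
    return parcellation.label(parcel_id)
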