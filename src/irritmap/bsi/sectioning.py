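"""Shrinkage-corrected brain-sectioning coordinates.

Antigen-retrieval processing shrinks fixed brains, so stereotaxic atlas
coordinates must be rescaled before cutting blocks for histology.  The
scaling factor

    alpha = L / (a - p)

compares the measured specimen length L (mm) with the atlas
anterior-to-posterior extent (a - p, both in Bregma-referenced mm, anterior
positive).  Bregma-referenced atlas offsets then map linearly onto the
specimen: the anterior-cortex-to-Bregma distance B2 and the
Bregma-to-block-center distance l are atlas offsets multiplied by alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import GeometryError

__all__ = ["SectioningPlan", "shrink_factor", "atlas_to_specimen"]

# atlas anterior extent of the cortex, Bregma-referenced mm
ATLAS_ANTERIOR_MM = 5.6


def shrink_factor(length_mm: float, a_mm: float, p_mm: float) -> float:
    """alpha = L / (a - p); a must be anterior of p and L positive."""
    if a_mm <= p_mm:
        raise GeometryError("atlas anterior extent must exceed posterior extent")
    if length_mm <= 0:
        raise GeometryError("specimen length must be positive")
    return length_mm / (a_mm - p_mm)


def atlas_to_specimen(atlas_offset_mm: float | np.ndarray, alpha: float):
    """Scale a Bregma-referenced atlas offset onto the shrunken specimen.

    Sign convention preserved: anterior positive, Bregma at the origin.
    """
    if alpha <= 0:
        raise GeometryError("alpha must be positive")
    return np.multiply(atlas_offset_mm, alpha)


@dataclass
class SectioningPlan:
    """Specimen-space block boundaries for one irritative zone.

    ``block_center_mm`` is the atlas Bregma offset of the target block
    center; B2 and l come out in specimen mm via alpha.
    """

    length_mm: float
    a_mm: float
    p_mm: float
    block_center_mm: float
    block_thickness_mm: float = 4.0

    def __post_init__(self) -> None:
        self.alpha = shrink_factor(self.length_mm, self.a_mm, self.p_mm)
        if not 0 < self.alpha <= 1.2:
            raise GeometryError(
                f"alpha {self.alpha:.3f} outside (0, 1.2]: check L, a, p"
            )

    @property
    def b2_mm(self) -> float:
        """Specimen distance from the most anterior cortex to Bregma."""
        return float(atlas_to_specimen(self.a_mm, self.alpha))

    @property
    def l_mm(self) -> float:
        """Specimen distance from Bregma to the block center (signed)."""
        return float(atlas_to_specimen(self.block_center_mm, self.alpha))

    def block_bounds(self) -> tuple[float, float]:
        half = self.alpha * self.block_thickness_mm / 2.0
        return (self.l_mm - half, self.l_mm + half)

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.block_bounds()
        return pd.DataFrame(
            [
                {
                    "alpha": self.alpha,
                    "B2_mm": self.b2_mm,
                    "l_mm": self.l_mm,
                    "block_anterior_mm": hi,
                    "block_posterior_mm": lo,
                }
            ]
        )
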