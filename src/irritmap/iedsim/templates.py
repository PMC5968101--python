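"""Interictal-discharge waveform templates.

IEDs come in two kinds distinguished by duration: spikes (20-70 ms) and
sharp-waves (70-200 ms).  The template is an asymmetric bi-Gaussian — a fast
rising limb and a slower decaying limb — parameterized so that the
full-width-at-half-maximum equals the requested duration exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import TemplateError

__all__ = ["IEDTemplate", "make_ied_template", "DURATION_BANDS"]

# closed-left duration bands (ms); 70 ms belongs to sharp_wave
DURATION_BANDS = {"spike": (20.0, 70.0), "sharp_wave": (70.0, 200.0)}

_HALF_WIDTH_FACTOR = np.sqrt(2.0 * np.log(2.0))


@dataclass
class IEDTemplate:
    """Unit-peak IED waveform at a given sampling rate."""

    kind: str
    duration_ms: float
    sampling_rate: float
    asymmetry: float
    waveform: np.ndarray
    peak_index: int

    @property
    def n_samples(self) -> int:
        return self.waveform.size

    def fwhm_ms(self) -> float:
        """Measured full width at half maximum of the waveform (ms)."""
        w = np.abs(self.waveform)
        half = 0.5 * w.max()
        above = np.where(w >= half)[0]
        return (above[-1] - above[0]) / self.sampling_rate * 1000.0


def make_ied_template(
    kind: str,
    duration_ms: float,
    sampling_rate: float,
    asymmetry: float = 2.0,
    support_factor: float = 4.0,
) -> IEDTemplate:
    """Build a unit-peak bi-Gaussian IED template.

    Parameters
    ----------
    kind : {"spike", "sharp_wave"}
    duration_ms : FWHM of the waveform; must lie within the kind's band
        ([20, 70) ms for spikes, [70, 200] ms for sharp-waves).
    asymmetry : ratio of decay to rise Gaussian widths (> 0); 1 is symmetric.
    support_factor : template support in units of the duration.
    """
    if kind not in DURATION_BANDS:
        raise TemplateError(f"unknown IED kind {kind!r}")
    lo, hi = DURATION_BANDS[kind]
    inside = lo <= duration_ms < hi if kind == "spike" else lo <= duration_ms <= hi
    if not inside:
        raise TemplateError(
            f"{kind} duration {duration_ms} ms outside band [{lo}, {hi}] ms"
        )
    if asymmetry <= 0:
        raise TemplateError("asymmetry must be positive")

    # rise/decay sigmas (ms): FWHM = (s_rise + s_decay) * sqrt(2 ln 2)
    s_rise = duration_ms / ((1.0 + asymmetry) * _HALF_WIDTH_FACTOR)
    s_decay = asymmetry * s_rise

    half_support = support_factor * duration_ms / 2.0
    dt_ms = 1000.0 / sampling_rate
    n_half = int(round(half_support / dt_ms))
    t = np.arange(-n_half, n_half + 1) * dt_ms
    wave = np.where(
        t < 0,
        np.exp(-0.5 * (t / s_rise) ** 2),
        np.exp(-0.5 * (t / s_decay) ** 2),
    )
    return IEDTemplate(
        kind=kind,
        duration_ms=duration_ms,
        sampling_rate=sampling_rate,
        asymmetry=asymmetry,
        waveform=wave,
        peak_index=n_half,
    )
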