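"""Zero-phase band-pass and notch filtering.

The classification pipeline uses two analysis streams: 15-50 Hz for spikes
and 5-15 Hz for sharp-waves.  Filters are 4th-order Butterworth sections
applied forward-backward (zero phase); an optional notch removes mains
interference.
"""

from __future__ import annotations

import numpy as np
import scipy.signal

from ..errors import FilterError
from ..recording import Recording

__all__ = ["bandpass", "SPIKE_BAND", "SHARP_WAVE_BAND"]

SPIKE_BAND = (15.0, 50.0)
SHARP_WAVE_BAND = (5.0, 15.0)


def bandpass(
    rec: Recording,
    low_hz: float,
    high_hz: float,
    notch_hz: float | None = None,
    order: int = 4,
) -> Recording:
    """Zero-phase Butterworth band-pass (and optional notch) filter.

    Returns a new :class:`Recording` whose ``band`` metadata records the
    pass band.  Band edges must satisfy 0 < low < high < Nyquist.
    """
    nyq = rec.sampling_rate / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise FilterError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz"
        )
    sos = scipy.signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=rec.sampling_rate, output="sos"
    )
    data = scipy.signal.sosfiltfilt(sos, rec.data, axis=1)
    if notch_hz is not None:
        if not 0 < notch_hz < nyq:
            raise FilterError(f"notch {notch_hz} Hz outside (0, Nyquist)")
        b, a = scipy.signal.iirnotch(notch_hz, Q=30.0, fs=rec.sampling_rate)
        data = scipy.signal.filtfilt(b, a, data, axis=1)
    return rec.copy_with(data=np.ascontiguousarray(data), band=(low_hz, high_hz))
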