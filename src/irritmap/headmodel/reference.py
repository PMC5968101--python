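"""Average-reference transform for recordings and lead fields.

EEG potentials are only defined up to a reference; the minimum-norm inverse
used downstream assumes data and gain matrix share the average reference.
The transform subtracts the across-electrode mean and is idempotent.
"""

from __future__ import annotations

import numpy as np

from ..errors import ReferenceError_
from ..recording import Recording
from .leadfield import LeadField

__all__ = ["apply_average_reference"]


def apply_average_reference(x: Recording | LeadField) -> Recording | LeadField:
    """Re-reference a :class:`Recording` or :class:`LeadField` to the average.

    Rows (electrodes) of the data / gain matrix have their per-column mean
    removed, so every column sums to zero afterwards.  Applying the transform
    twice equals applying it once.
    """
    if isinstance(x, Recording):
        if x.n_channels < 2:
            raise ReferenceError_("average reference needs at least 2 electrodes")
        data = x.data - x.data.mean(axis=0, keepdims=True)
        return x.copy_with(data=data, referenced=True)
    if isinstance(x, LeadField):
        if x.n_electrodes < 2:
            raise ReferenceError_("average reference needs at least 2 electrodes")
        gain = x.gain - x.gain.mean(axis=0, keepdims=True)
        return LeadField(gain, x.n_sources, x.orientation, referenced=True)
    raise TypeError(f"cannot average-reference object of type {type(x).__name__}")


def average_reference_operator(n: int) -> np.ndarray:
    """The centering matrix H = I - 11^T/n acting on electrode vectors."""
    if n < 2:
        raise ReferenceError_("average reference needs at least 2 electrodes")
    return np.eye(n) - np.full((n, n), 1.0 / n)
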