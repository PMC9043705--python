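"""Angular arithmetic helpers.

All angles are in degrees, counterclockwise positive, screen frame.
Deviations are treated linearly after wrapping to (-180, 180]; the
analysis never needs circular statistics because all deviations of
interest are well inside one half-turn.
"""
from __future__ import annotations

import numpy as np


def wrap_deg(a):
    """Wrap angle(s) to the interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def ang_diff(a, b):
    """Signed angular difference a - b, wrapped to (-180, 180]."""
    return wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
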