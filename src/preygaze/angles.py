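"""Angle conventions and helpers.

All public angles are in degrees. Wrapped angles live in (-180, 180]; yaw is
measured counter-clockwise (viewed from above) from the arena +x axis.
Unwrapped angle series are used internally wherever velocities or
interpolation are involved, so that the -180/+180 seam never produces
spurious 360 degree jumps.
"""

from __future__ import annotations

import numpy as np


def wrap_degrees(x):
    """Wrap angle(s) in degrees into (-180, 180]."""
    x = np.asarray(x, dtype=float)
    wrapped = 180.0 - np.mod(180.0 - x, 360.0)
    return wrapped if wrapped.ndim else float(wrapped)


def unwrap_degrees(x):
    """Unwrap a degree series along the real line (period 360)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    valid = np.isfinite(x)
    out = np.full_like(x, np.nan)
    if valid.any():
        out[valid] = np.unwrap(x[valid], period=360.0)
    return out
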