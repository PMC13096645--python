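"""Degree-valued angle helpers.

All angles in the package are degrees, wrapped to (-180, 180], with positive
turns clockwise (to the animal's right).
"""

from __future__ import annotations

import numpy as np


def wrap_deg(angle):
    """Wrap angle(s) in degrees to the half-open interval (-180, 180].

    Accepts scalars or arrays; -180 maps to +180.
    """
    return 180.0 - np.mod(180.0 - np.asarray(angle, dtype=float), 360.0)


def circular_diff_deg(a, b):
    """Signed smallest difference a - b in degrees, in (-180, 180]."""
    return wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
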