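"""Circular helpers for 180°-periodic orientation space.

Bar tilts live in (−90°, +90°]; orientations 180° apart are identical.
All mixture-model machinery elsewhere works on doubled angles (×2, in
radians), which maps the orientation space onto the full circle.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_orientation",
    "signed_orientation_diff",
    "orientation_error",
    "to_doubled_radians",
    "from_doubled_radians",
]


def wrap_orientation(deg):
    """Wrap angles (degrees) into the orientation interval (−90, +90]."""
    deg = np.asarray(deg, dtype=float)
    return 90.0 - np.mod(90.0 - deg, 180.0)


def signed_orientation_diff(a, b):
    """Signed acute difference a − b in orientation space, in (−90, +90].

    Positive values mean ``a`` is anticlockwise of ``b``.
    """
    return wrap_orientation(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def orientation_error(reported, target):
    """Absolute reproduction error in degrees, in [0, 90].

    The acute-angle absolute difference between two orientations; the
    maximum possible error is 90° and the chance level (uniform random
    reports against uniform targets) is 45°.
    """
    return np.abs(signed_orientation_diff(reported, target))


def to_doubled_radians(deg):
    """Map orientation degrees onto the full circle: 2·θ in radians."""
    return np.deg2rad(2.0 * np.asarray(deg, dtype=float))


def from_doubled_radians(rad):
    """Inverse of :func:`to_doubled_radians`, wrapped to (−90, +90]."""
    return wrap_orientation(np.rad2deg(np.asarray(rad, dtype=float)) / 2.0)
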