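"""Angle conventions and folding helpers.

All angles are in degrees. Pixel coordinates follow the image convention:
origin at the top-left pixel center, x increasing along columns, y along
rows. Directions are measured from the +x axis toward the +y axis
(``atan2(dy, dx)``) and normalized to [0, 360). Axes (undirected lines such
as the mask major axis) live in [0, 180).
"""

from __future__ import annotations

import numpy as np


def direction_deg(dx: float, dy: float) -> float:
    """Direction of the vector (dx, dy), in [0, 360)."""
    return float(np.degrees(np.arctan2(dy, dx)) % 360.0)


def fold_axis(angle: float) -> float:
    """Normalize an undirected axis angle into [0, 180)."""
    return float(angle % 180.0)


def angle_between_directions(a: float, b: float) -> float:
    """Absolute difference of two directions folded into [0, 180]."""
    d = abs(a - b) % 360.0
    return float(360.0 - d if d > 180.0 else d)


def angle_to_axis(direction: float, axis: float) -> float:
    """Acute angle between a direction and an undirected axis, in [0, 90]."""
    d = (direction - axis) % 180.0
    return float(180.0 - d if d > 90.0 else d)


def angular_distance(a: float, b: float) -> float:
    """Shortest angular distance between two directions, in [0, 180]."""
    return angle_between_directions(a, b)
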