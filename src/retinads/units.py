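"""Unit conversions for retinal stimulus geometry.

Retinal magnification in macaque is taken as 223 µm of retina per degree of
visual angle, so a bar drifting at 500 µm/s corresponds to ~2.24 deg/s.
"""

MACAQUE_UM_PER_DEG: float = 223.0
"""Macaque retinal magnification (µm of retina per degree of visual angle)."""

UM2_PER_MM2: float = 1e6
MM2_PER_UM2: float = 1e-6


def um_s_to_deg_s(speed_um_s: float, um_per_deg: float = MACAQUE_UM_PER_DEG) -> float:
    """Convert a retinal speed in µm/s to degrees of visual angle per second."""
    return speed_um_s / um_per_deg


def deg_s_to_um_s(speed_deg_s: float, um_per_deg: float = MACAQUE_UM_PER_DEG) -> float:
    """Convert a speed in degrees of visual angle per second to µm/s on the retina."""
    return speed_deg_s * um_per_deg
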