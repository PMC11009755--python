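"""Physical pixel scales and unit conversions.

At 10x magnification the HQ camera resolves a 2.38 x 1.38 mm field of view
onto 1920 x 1088 pixels, i.e. 1.25 um per pixel edge.  The earlier-generation
sensor at the same magnification resolved 3.75 um per pixel edge; the ratio
of the two is the linear resolution gain of the upgrade.
"""

from __future__ import annotations

#: Camera pixel edge length at 10x with the HQ sensor (um per px).
PIXEL_SIZE_UM = 1.25

#: Pixel edge length of the earlier-generation sensor at 10x (um per px).
LEGACY_PIXEL_SIZE_UM = 3.75

__all__ = [
    "PIXEL_SIZE_UM",
    "LEGACY_PIXEL_SIZE_UM",
    "um_to_px",
    "px_to_um",
    "linear_resolution_gain",
]


def um_to_px(um: float, pixel_size_um: float = PIXEL_SIZE_UM) -> float:
    """Convert a physical length in micrometres to camera pixels."""
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    return um / pixel_size_um


def px_to_um(px: float, pixel_size_um: float = PIXEL_SIZE_UM) -> float:
    """Convert a length in camera pixels to micrometres."""
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    return px * pixel_size_um


def linear_resolution_gain(
    old_pixel_um: float = LEGACY_PIXEL_SIZE_UM,
    new_pixel_um: float = PIXEL_SIZE_UM,
) -> float:
    """Linear resolution improvement factor between two pixel scales."""
    if old_pixel_um <= 0 or new_pixel_um <= 0:
        raise ValueError("pixel sizes must be positive")
    return old_pixel_um / new_pixel_um
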