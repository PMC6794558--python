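"""Screen geometry and visual-angle conversions.

Screen-based eye trackers report gaze in a pixel raster whose physical size
and viewing distance determine the mapping between pixels and degrees of
visual angle.  All downstream thresholds that are naturally expressed in
degrees (measurement noise, fixation-merge radii) are converted to pixels
through :func:`pixels_per_degree`.

Coordinate convention: origin at the top-left corner of the raster, x
rightward, y downward, units pixels, 0-based, half-open bounds
``[0, width) x [0, height)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ScreenGeometry", "TrialWindow", "pixels_per_degree"]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical and raster description of the stimulus screen.

    Parameters
    ----------
    raster_width, raster_height
        Raster size in pixels.
    physical_width_cm, physical_height_cm
        Physical size of the display area in centimetres.
    viewing_distance_cm
        Eye-to-screen distance in centimetres.
    """

    raster_width: int
    raster_height: int
    physical_width_cm: float
    physical_height_cm: float
    viewing_distance_cm: float

    def __post_init__(self) -> None:
        for name in (
            "raster_width",
            "raster_height",
            "physical_width_cm",
            "physical_height_cm",
            "viewing_distance_cm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"ScreenGeometry.{name} must be strictly positive")
        pitch_x = self.physical_width_cm / self.raster_width
        pitch_y = self.physical_height_cm / self.raster_height
        ratio = pitch_x / pitch_y
        if not (0.5 <= ratio <= 2.0):
            raise ValueError(
                "anisotropic pixel pitch: horizontal and vertical pitch differ "
                f"by more than a factor of 2 (ratio {ratio:.3g})"
            )

    @property
    def screen_area_px(self) -> float:
        return float(self.raster_width) * float(self.raster_height)

    def contains(self, x, y) -> bool:
        """Half-open on-screen test for scalar coordinates."""
        return 0 <= x < self.raster_width and 0 <= y < self.raster_height

    def pixels_per_degree(self, axis: str = "horizontal") -> float:
        return pixels_per_degree(self, axis=axis)


def pixels_per_degree(geometry: ScreenGeometry, axis: str = "horizontal") -> float:
    """Pixels subtended by one degree of visual angle at screen centre.

    Uses the exact small-patch formula ``d * tan(1 deg) / pitch`` where
    ``pitch`` is the physical size of one pixel along the chosen axis and
    ``d`` the viewing distance.

    Parameters
    ----------
    geometry
        Validated screen geometry.
    axis
        ``"horizontal"``, ``"vertical"`` or ``"mean"`` (arithmetic mean of
        the two axes, used for isotropic radii).
    """
    tan1 = math.tan(math.radians(1.0))
    px_h = (
        geometry.raster_width * geometry.viewing_distance_cm * tan1 / geometry.physical_width_cm
    )
    px_v = (
        geometry.raster_height
        * geometry.viewing_distance_cm
        * tan1
        / geometry.physical_height_cm
    )
    if axis == "horizontal":
        return px_h
    if axis == "vertical":
        return px_v
    if axis == "mean":
        return 0.5 * (px_h + px_v)
    raise ValueError(f"unknown axis {axis!r}")


@dataclass(frozen=True)
class TrialWindow:
    """Time window of one stimulus presentation within a recording."""

    stimulus_id: str
    start: float  # ms
    end: float  # ms

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("TrialWindow.end must be greater than start")

    @property
    def duration(self) -> float:
        return self.end - self.start
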