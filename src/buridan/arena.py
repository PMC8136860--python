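"""Arena geometry for Buridan's paradigm.

The assay platform is a water-surrounded disc; two high-contrast vertical
stripes sit diametrically opposed outside the platform and serve as the
fixation targets. All coordinates are in millimetres in a platform-centred
frame with the stripe axis along +x/-x by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError


@dataclass(frozen=True)
class ArenaGeometry:
    """Geometry of the Buridan arena.

    Parameters
    ----------
    platform_radius : float
        Radius of the walking platform in mm (default 58.5, i.e. a
        117-mm-diameter platform).
    stripe_distance : float
        Distance from the platform centre to each stripe centre, mm.
    stripe_width : float
        Stripe width, mm.
    stripe_height : float
        Stripe height, mm. Carried as metadata only; the analysis treats
        stripes as point targets at their centres.
    stripe_axis_angle : float
        Orientation of the stripe axis in radians; the two stripes sit at
        ``+-stripe_distance`` along this axis.
    """

    platform_radius: float = 58.5
    stripe_distance: float = 146.5
    stripe_width: float = 30.0
    stripe_height: float = 320.0
    stripe_axis_angle: float = 0.0

    def __post_init__(self) -> None:
        if not self.platform_radius > 0:
            raise ConfigError("platform_radius must be > 0")
        if not self.stripe_distance > self.platform_radius:
            raise ConfigError("stripe_distance must exceed platform_radius")
        if not self.stripe_width > 0:
            raise ConfigError("stripe_width must be > 0")

    @property
    def stripe_centers(self) -> np.ndarray:
        """(2, 2) array of the two stripe-centre coordinates (mm)."""
        c, s = np.cos(self.stripe_axis_angle), np.sin(self.stripe_axis_angle)
        d = self.stripe_distance
        return np.array([[d * c, d * s], [-d * c, -d * s]])

    def rotated(self, angle: float) -> "ArenaGeometry":
        """Return the same arena with the stripe axis rotated by *angle* rad."""
        return ArenaGeometry(
            self.platform_radius,
            self.stripe_distance,
            self.stripe_width,
            self.stripe_height,
            self.stripe_axis_angle + angle,
        )

    def scaled(self, factor: float) -> "ArenaGeometry":
        """Return the arena with all lengths multiplied by *factor*."""
        return ArenaGeometry(
            self.platform_radius * factor,
            self.stripe_distance * factor,
            self.stripe_width * factor,
            self.stripe_height * factor,
            self.stripe_axis_angle,
        )
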