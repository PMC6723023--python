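"""CIELAB color coordinates of fruit pulp and derived chroma/hue.

The CIE L*a*b* space encodes lightness L* in [0, 100] and two unbounded
chromatic axes: a* (green negative, red positive) and b* (blue negative,
yellow positive).  Chroma C* = sqrt(a*^2 + b*^2) is the radial color
intensity and hue h is the angular position of (a*, b*), reported in
degrees in [0, 360).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ValidationError


@dataclass(frozen=True)
class ColorTriplet:
    """One pulp color measurement (L*, a*, b*).

    Parameters
    ----------
    L_star : lightness, must lie in [0, 100].
    a_star : red/green axis, unbounded.
    b_star : yellow/blue axis, unbounded.
    """

    L_star: float
    a_star: float
    b_star: float

    def __post_init__(self) -> None:
        for name in ("L_star", "a_star", "b_star"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValidationError(f"{name} must be finite, got {value!r}")
        if not 0.0 <= self.L_star <= 100.0:
            raise ValidationError(
                f"L_star must lie in [0, 100], got {self.L_star!r}"
            )

    @property
    def chroma(self) -> float:
        return math.hypot(self.a_star, self.b_star)

    @property
    def hue(self) -> float:
        """Hue angle in degrees, mapped to [0, 360); 0 when chroma is 0."""
        if self.chroma == 0.0:
            return 0.0
        return math.degrees(math.atan2(self.b_star, self.a_star)) % 360.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.L_star, self.a_star, self.b_star)


def chroma_hue(color: ColorTriplet) -> tuple[float, float]:
    """Return (chroma, hue in degrees) for one color measurement."""
    return (color.chroma, color.hue)
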