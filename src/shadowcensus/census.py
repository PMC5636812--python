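"""Solar-shadow photogrammetry: from shadow-pixel totals to a penguin census.

At high southern latitudes the sun stays low, so a standing penguin casts a
long shadow that covers far more image area than the bird itself.  The chain
here is:

1. solar geometry — zenith angle z from latitude θ, declination δ and hour
   angle ω via ``cos z = sin θ sin δ + cos θ cos δ cos ω``, elevation
   α = 90° − z;
2. shadow model — the expected shadow footprint of one bird is a rectangle
   of ground length H/tan α (H the bird's height) and width W (chest
   width), giving p = (H/tan α)·W / R² shadow pixels per bird at ground
   resolution R;
3. census — total shadow pixels divided by p, rounded to the nearest bird.

Latitudes are signed (south negative).  All lengths are handled in
centimetres internally; resolutions quoted in metres are converted at the
interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SolarGeometry",
    "ShadowModelParams",
    "hour_angle",
    "solar_zenith",
    "solar_elevation",
    "pixels_per_penguin",
    "estimate_population",
    "percent_change",
    "census_from_pixels",
]


def hour_angle(l_d: float, l: float) -> float:
    """Solar hour angle ω = l_d − l (degrees), normalized to (−180, 180].

    ``l_d`` is the longitude of the subsolar point and ``l`` the local
    longitude, both in [−180, 180].
    """
    for name, v in (("l_d", l_d), ("l", l)):
        if not -180.0 <= v <= 180.0:
            raise ValueError(f"{name} must lie in [-180, 180], got {v}")
    omega = l_d - l
    omega = math.fmod(omega, 360.0)
    if omega <= -180.0:
        omega += 360.0
    elif omega > 180.0:
        omega -= 360.0
    return omega


def solar_zenith(theta: float, delta: float, omega: float) -> float:
    """Solar zenith angle z (degrees) from latitude θ, declination δ and
    hour angle ω, all in degrees.  The arccos argument is clamped to
    [−1, 1] against floating-point rounding."""
    th, de, om = map(math.radians, (theta, delta, omega))
    cos_z = math.sin(th) * math.sin(de) + math.cos(th) * math.cos(de) * math.cos(om)
    cos_z = min(1.0, max(-1.0, cos_z))
    return math.degrees(math.acos(cos_z))


def solar_elevation(theta: float, delta: float, omega: float) -> float:
    """Solar elevation α = 90° − z (degrees)."""
    return 90.0 - solar_zenith(theta, delta, omega)


@dataclass(frozen=True)
class SolarGeometry:
    """Sun position inputs for one acquisition.

    theta : local latitude, degrees, signed (south negative)
    delta : solar declination, degrees (|δ| ≤ 23.45); taken from a
            declination table for the acquisition date
    omega : solar hour angle, degrees; 0 at local solar noon
    """

    theta: float
    delta: float
    omega: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.delta) > 23.45:
            raise ValueError(f"|delta| must be <= 23.45 degrees, got {self.delta}")
        if not -90.0 <= self.theta <= 90.0:
            raise ValueError(f"latitude must lie in [-90, 90], got {self.theta}")

    @property
    def zenith(self) -> float:
        return solar_zenith(self.theta, self.delta, self.omega)

    @property
    def elevation(self) -> float:
        return 90.0 - self.zenith


@dataclass(frozen=True)
class ShadowModelParams:
    """Shadow-footprint model parameters (lengths in centimetres).

    H : average penguin height, cm (adult Adélie ≈ 46–61 cm; default 53.5)
    W : average chest width, cm (≈ 15–25 cm; default 20)
    R : image ground resolution, cm per pixel
    """

    H: float = 53.5
    W: float = 20.0
    R: float = 10.0

    def __post_init__(self) -> None:
        if min(self.H, self.W, self.R) <= 0:
            raise ValueError("H, W and R must all be positive")

    @classmethod
    def from_metres(
        cls, height_m: float = 0.535, width_m: float = 0.20, resolution_m: float = 0.10
    ) -> "ShadowModelParams":
        return cls(H=height_m * 100.0, W=width_m * 100.0, R=resolution_m * 100.0)

    def pixels_per_penguin(self, alpha: float) -> float:
        return pixels_per_penguin(self.H, self.W, alpha, self.R)


def pixels_per_penguin(H: float, W: float, alpha: float, R: float) -> float:
    """Mean shadow pixels per bird, p = (H / tan α) · W / R².

    H, W and R share one length unit (conventionally cm); α is the solar
    elevation in degrees and must lie strictly between 0° and 90° for the
    shadow to be finite and non-degenerate.
    """
    if not 0.0 < alpha < 90.0:
        raise ValueError(
            f"solar elevation must lie strictly in (0, 90) degrees, got {alpha}"
        )
    if min(H, W, R) <= 0:
        raise ValueError("H, W and R must all be positive")
    return (H / math.tan(math.radians(alpha))) * W / (R * R)


def estimate_population(total_shadow_pixels: int, p: float) -> int:
    """Census: total shadow pixels / p, rounded to the nearest integer."""
    if total_shadow_pixels < 0:
        raise ValueError("total_shadow_pixels must be non-negative")
    if not p > 0:
        raise ValueError(f"p must be positive, got {p}")
    # round-half-up matches how the censuses are conventionally reported
    return int(math.floor(total_shadow_pixels / p + 0.5))


def percent_change(n_old: float, n_new: float) -> float:
    """Percent change 100·(n_new − n_old)/n_old (report rounded to integer)."""
    if n_old <= 0:
        raise ValueError("n_old must be positive")
    return 100.0 * (n_new - n_old) / n_old


def census_from_pixels(
    total_shadow_pixels: int,
    params: ShadowModelParams,
    alpha: float,
    round_p: bool = True,
) -> tuple[int, float]:
    """Full census chain: shadow model → p → population.

    p is rounded to one decimal before the division by default, the
    precision at which a per-bird pixel count is meaningfully reported;
    returns (population, p_used).
    """
    p = params.pixels_per_penguin(alpha)
    if round_p:
        p = round(p, 1)
    return estimate_population(total_shadow_pixels, p), p
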