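"""Geometric model of the anterior cornea and the scan/wound specifications.

The anterior corneal surface is modelled as a spherical cap of radius of
curvature ``R`` (mm).  In scan coordinates (lateral ``x``/``y`` in mm from the
volume corner is handled by :class:`ScanSpec`; the model itself works in mm
relative to the field centre) the surface depth below the top of the scan
volume is

    z(x, y) = apex_depth + R - sqrt(R^2 - rho^2),    rho^2 = (x-x0)^2 + (y-y0)^2

which is defined only for ``rho < R``.  A circular epithelial debridement of
chord diameter ``d`` on this sphere has planar (projected) area ``pi (d/2)^2``
and true surface area equal to the spherical-cap area
``2 pi R^2 (1 - sqrt(1 - (d/2R)^2))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "OutsideValidDomain",
    "CorneaModel",
    "ScanSpec",
    "WoundSpec",
    "make_cornea_model",
    "spherical_cap_area",
]


class ValidationError(ValueError):
    """A parameter container was constructed with invalid values."""


class OutsideValidDomain(ValueError):
    """A lateral position lies outside the spherical model's valid domain (rho >= R)."""


def spherical_cap_area(radius_of_curvature: float, chord_radius: float) -> float:
    """Surface area of a spherical cap of chord radius ``r`` on a sphere of radius ``R``.

    ``A = 2 pi R^2 (1 - sqrt(1 - r^2/R^2))``; both arguments in mm, result in mm^2.
    """
    R, r = float(radius_of_curvature), float(chord_radius)
    if not 0.0 <= r < R:
        raise OutsideValidDomain(f"chord radius {r} mm must satisfy 0 <= r < R = {R} mm")
    return 2.0 * math.pi * R * R * (1.0 - math.sqrt(1.0 - (r / R) ** 2))


@dataclass(frozen=True)
class CorneaModel:
    """Spherical-cap model of the anterior corneal surface.

    Parameters
    ----------
    radius_of_curvature : float
        Anterior radius of curvature in mm.  Default 7.5 mm (typical rabbit
        anterior cornea); every curvature-dependent result records the value
        actually used.
    apex_offset : (float, float)
        Lateral position of the corneal apex relative to the field centre, mm.
    apex_depth : float
        Axial position of the apex below the top of the scan volume, mm.
    epithelium_thickness : float
        Epithelial thickness in micrometres (rabbit-typical 40 um).
    refractive_scaling : float
        Dimensionless factor applied to axial distances.  Default 1.0: volumes
        are assumed already geometrically corrected.
    """

    radius_of_curvature: float = 7.5
    apex_offset: tuple[float, float] = (0.0, 0.0)
    apex_depth: float = 0.1
    epithelium_thickness: float = 40.0
    refractive_scaling: float = 1.0

    def __post_init__(self) -> None:
        if not self.radius_of_curvature > 0:
            raise ValidationError("radius_of_curvature must be > 0")
        if not self.epithelium_thickness > 0:
            raise ValidationError("epithelium_thickness must be > 0")
        if not self.refractive_scaling > 0:
            raise ValidationError("refractive_scaling must be > 0")
        if len(self.apex_offset) != 2:
            raise ValidationError("apex_offset must be (x, y)")

    def rho(self, x, y):
        """Lateral distance from the apex, mm (array-aware)."""
        x0, y0 = self.apex_offset
        return np.hypot(np.asarray(x, dtype=float) - x0, np.asarray(y, dtype=float) - y0)

    def sagitta(self, rho):
        """Sphere sagitta ``R - sqrt(R^2 - rho^2)`` in mm; NaN where rho >= R."""
        R = self.radius_of_curvature
        rho = np.asarray(rho, dtype=float)
        with np.errstate(invalid="ignore"):
            s = R - np.sqrt(np.maximum(R * R - rho * rho, 0.0))
        return np.where(rho < R, s, np.nan)

    def surface_depth(self, x, y):
        """Anterior-surface depth z(x, y) below the top of the scan volume, mm.

        NaN outside the valid domain (rho >= R).
        """
        return self.apex_depth + self.sagitta(self.rho(x, y)) * self.refractive_scaling


def make_cornea_model(
    radius_mm: float,
    apex_offset: tuple[float, float] = (0.0, 0.0),
    epithelium_um: float = 40.0,
    apex_depth_mm: float = 0.1,
) -> CorneaModel:
    """Validated constructor for :class:`CorneaModel` (radius in mm, epithelium in um)."""
    return CorneaModel(
        radius_of_curvature=float(radius_mm),
        apex_offset=(float(apex_offset[0]), float(apex_offset[1])),
        apex_depth=float(apex_depth_mm),
        epithelium_thickness=float(epithelium_um),
    )


@dataclass(frozen=True)
class ScanSpec:
    """Physical extent and sampling of an OCT volume.

    Defaults are the acquisition geometry the pipeline targets: a
    7.5 x 7.5 x 1 mm (horizontal x vertical x depth) volume comprising
    1024 x 512 x 1024 pixels.  Pixel centres sit at ``(i + 0.5) * pitch`` from
    the volume corner; depth increases away from the instrument.
    """

    extent: tuple[float, float, float] = (7.5, 7.5, 1.0)
    samples: tuple[int, int, int] = (1024, 512, 1024)

    def __post_init__(self) -> None:
        if len(self.extent) != 3 or len(self.samples) != 3:
            raise ValidationError("extent and samples must be 3-tuples (x, y, z)")
        if not all(e > 0 for e in self.extent):
            raise ValidationError("all extents must be > 0")
        if not all(int(n) == n and n > 0 for n in self.samples):
            raise ValidationError("all sample counts must be positive integers")

    @property
    def pitch(self) -> tuple[float, float, float]:
        """Pixel pitches (dx, dy, dz) in mm."""
        return tuple(e / n for e, n in zip(self.extent, self.samples))

    @property
    def pixel_area_mm2(self) -> float:
        """Lateral pixel area dx * dy in mm^2."""
        dx, dy, _ = self.pitch
        return dx * dy

    def axis_centers(self, axis: int, centered: bool = True) -> np.ndarray:
        """Pixel-centre coordinates along one axis (0=x, 1=y, 2=z), mm.

        ``centered=True`` puts the origin at the field centre for lateral axes
        (the cornea model's frame); the depth axis always starts at 0.
        """
        n = self.samples[axis]
        d = self.extent[axis] / n
        c = (np.arange(n) + 0.5) * d
        if centered and axis != 2:
            c -= self.extent[axis] / 2.0
        return c

    def lateral_grid(self, centered: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (X, Y) of lateral pixel centres, shape (nx, ny), mm."""
        x = self.axis_centers(0, centered)
        y = self.axis_centers(1, centered)
        return np.meshgrid(x, y, indexing="ij")

    @classmethod
    def reduced(cls, n: int = 256, extent: tuple[float, float, float] = (7.5, 7.5, 1.0)) -> "ScanSpec":
        """Isotropically sampled reduced-resolution spec over the same physical extent."""
        return cls(extent=extent, samples=(n, n, n))


@dataclass(frozen=True)
class WoundSpec:
    """Circular (optionally irregular) epithelial debridement footprint.

    The trephine diameter is interpreted as the planar chord diameter of the
    wound footprint: a rigid trephine contacts the spherical cornea on a planar
    circle.  ``irregularity`` perturbs the boundary radius with a few low-order
    harmonics (amplitude as a fraction of the radius) to emulate manual
    debridement; it is a convenience, not calibrated to any measured shape.
    """

    center: tuple[float, float] = (0.0, 0.0)
    chord_diameter: float = 6.0
    shape: str = "circle"
    irregularity: float = 0.0
    irregularity_seed: int = 0

    def __post_init__(self) -> None:
        if not self.chord_diameter >= 0:
            raise ValidationError("chord_diameter must be >= 0")
        if self.shape not in ("circle", "irregular"):
            raise ValidationError("shape must be 'circle' or 'irregular'")
        if self.shape == "irregular" and not 0 <= self.irregularity < 0.5:
            raise ValidationError("irregularity must be in [0, 0.5)")

    @property
    def radius(self) -> float:
        return self.chord_diameter / 2.0

    @property
    def planar_area(self) -> float:
        """True planar (projected) area pi r^2 of the circular footprint, mm^2."""
        return math.pi * self.radius**2

    def cap_area(self, radius_of_curvature: float) -> float:
        """True surface area of the wound on a sphere of radius R, mm^2."""
        if self.radius == 0:
            return 0.0
        return spherical_cap_area(radius_of_curvature, self.radius)

    def _boundary_radius(self, theta: np.ndarray) -> np.ndarray:
        r = np.full_like(theta, self.radius, dtype=float)
        if self.shape == "irregular" and self.irregularity > 0:
            rng = np.random.default_rng(self.irregularity_seed)
            for k in (2, 3, 5):
                amp = self.irregularity * self.radius * rng.uniform(0.2, 1.0) / 3.0
                r += amp * np.cos(k * theta + rng.uniform(0, 2 * math.pi))
        return r

    def footprint(self, scan: ScanSpec) -> np.ndarray:
        """Boolean en face footprint mask on the scan's lateral grid, shape (nx, ny)."""
        X, Y = scan.lateral_grid()
        dx_, dy_ = X - self.center[0], Y - self.center[1]
        if self.shape == "circle" or self.irregularity == 0:
            return dx_ * dx_ + dy_ * dy_ < self.radius**2
        theta = np.arctan2(dy_, dx_)
        return np.hypot(dx_, dy_) < self._boundary_radius(theta)

    def check_fits(self, scan: ScanSpec) -> None:
        """Raise if the wound footprint leaves the lateral scan field."""
        cx, cy = self.center
        rmax = self.radius * (1 + self.irregularity)
        if (abs(cx) + rmax > scan.extent[0] / 2) or (abs(cy) + rmax > scan.extent[1] / 2):
            raise ValidationError(
                f"wound footprint (centre {self.center}, radius {self.radius} mm) "
                f"does not fit inside the {scan.extent[0]} x {scan.extent[1]} mm field"
            )
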