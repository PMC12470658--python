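"""Scan-grid geometry for macular cube OCT volumes.

A macular cube is a raster of ``n_slow`` B-scans, each holding ``n_fast``
A-scans, covering a rectangular en-face area centered (by default) on the
fovea.  The default geometry is the common 512 x 128 pattern over 6 x 6 mm,
which gives anisotropic en-face sampling: 11.72 um along the fast (B-scan)
axis and 46.88 um along the slow axis.  All zone geometry is expressed in
physical millimetres relative to the cube center, using a cell-center
convention, so the grid anisotropy is handled uniformly.

The fast axis is x and the slow axis is y.  For a right eye (OD) the nasal
direction is +x; for a left eye (OS) it is mirrored.  Only this relative
labelling matters for synthetic data; both are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .exceptions import GeometryError, ValidationError

LATERALITIES = ("OD", "OS")

#: Radius (mm) of the central-subfield disc around the fovea.
CENTRAL_SUBFIELD_RADIUS_MM = 0.5
#: Radius (mm) of the parafoveal disc around the fovea.
PARAFOVEAL_RADIUS_MM = 1.0


@dataclass(frozen=True)
class CubeGeometry:
    """Grid dimensions, physical extents and foveal position of one cube.

    Parameters
    ----------
    n_fast, n_slow
        A-scans per B-scan and number of B-scans (defaults 512, 128).
    extent_fast_mm, extent_slow_mm
        Physical en-face extents of the raster (defaults 6.0 x 6.0 mm).
    axial_um_per_px
        Axial sampling of the intensity frames in micrometres per pixel
        (default 1.95, i.e. ~2 mm depth over 1024 pixels).
    fovea_xy_mm
        En-face coordinates of the foveal center relative to the cube
        center; (0, 0) for a well-centered scan.
    laterality
        "OD" (right eye) or "OS" (left eye); resolves nasal vs temporal.
    """

    n_fast: int = 512
    n_slow: int = 128
    extent_fast_mm: float = 6.0
    extent_slow_mm: float = 6.0
    axial_um_per_px: float = 1.95
    fovea_xy_mm: tuple[float, float] = (0.0, 0.0)
    laterality: str = "OD"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fovea_xy_mm",
            (float(self.fovea_xy_mm[0]), float(self.fovea_xy_mm[1])),
        )
        if self.n_fast < 2 or self.n_slow < 2:
            raise ValidationError("grid must be at least 2 x 2 A-scans")
        if self.extent_fast_mm <= 0 or self.extent_slow_mm <= 0:
            raise ValidationError("en-face extents must be positive")
        if self.axial_um_per_px <= 0:
            raise ValidationError("axial sampling must be positive")
        if self.laterality not in LATERALITIES:
            raise ValidationError(
                f"laterality must be one of {LATERALITIES}, got {self.laterality!r}"
            )
        fx, fy = self.fovea_xy_mm
        # the 1.0 mm parafoveal disc must fit inside the scan
        if (abs(fx) + PARAFOVEAL_RADIUS_MM > self.extent_fast_mm / 2
                or abs(fy) + PARAFOVEAL_RADIUS_MM > self.extent_slow_mm / 2):
            raise GeometryError(
                "foveal center too decentered: the 1.0 mm parafoveal zone "
                "does not fit inside the cube"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        """(n_slow, n_fast) — the shape of every en-face grid."""
        return (self.n_slow, self.n_fast)

    @property
    def dx_mm(self) -> float:
        """Fast-axis cell pitch in mm."""
        return self.extent_fast_mm / self.n_fast

    @property
    def dy_mm(self) -> float:
        """Slow-axis cell pitch in mm."""
        return self.extent_slow_mm / self.n_slow

    @property
    def cell_area_mm2(self) -> float:
        return self.dx_mm * self.dy_mm

    @property
    def scan_area_mm2(self) -> float:
        return self.extent_fast_mm * self.extent_slow_mm

    @property
    def nasal_sign(self) -> int:
        """+1 if nasal is the +x direction (OD), -1 for OS."""
        return 1 if self.laterality == "OD" else -1

    def x_centers_mm(self) -> np.ndarray:
        """Fast-axis cell-center coordinates relative to the cube center."""
        return (np.arange(self.n_fast) + 0.5) * self.dx_mm - self.extent_fast_mm / 2

    def y_centers_mm(self) -> np.ndarray:
        """Slow-axis cell-center coordinates relative to the cube center."""
        return (np.arange(self.n_slow) + 0.5) * self.dy_mm - self.extent_slow_mm / 2

    def fovea_distance_mm(self) -> np.ndarray:
        """(n_slow, n_fast) grid of en-face distances to the foveal center."""
        return _fovea_distance_grid(self)


@lru_cache(maxsize=64)
def _fovea_distance_grid(geometry: CubeGeometry) -> np.ndarray:
    fx, fy = geometry.fovea_xy_mm
    x = geometry.x_centers_mm() - fx
    y = geometry.y_centers_mm() - fy
    grid = np.hypot(x[np.newaxis, :], y[:, np.newaxis])
    grid.setflags(write=False)
    return grid


@dataclass(frozen=True)
class ZoneSpec:
    """A circular analysis zone (disc) centered on the fovea."""

    name: str
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValidationError("zone radius must be positive")

    @classmethod
    def central_subfield(cls) -> "ZoneSpec":
        return cls("central_subfield", CENTRAL_SUBFIELD_RADIUS_MM)

    @classmethod
    def parafoveal(cls) -> "ZoneSpec":
        return cls("parafoveal", PARAFOVEAL_RADIUS_MM)


def zone_mask(geometry: CubeGeometry, zone: ZoneSpec,
              allow_clip: bool = False) -> np.ndarray:
    """Boolean en-face mask of grid points inside a foveal disc.

    A point is included iff the Euclidean distance from its cell center to
    the foveal center is <= ``zone.radius_mm``.  By default the whole disc
    must fit inside the scan; pass ``allow_clip=True`` to permit a zone that
    extends past the cube edge (the mask is then clipped).
    """
    fx, fy = geometry.fovea_xy_mm
    r = zone.radius_mm
    if not allow_clip:
        if (abs(fx) + r > geometry.extent_fast_mm / 2
                or abs(fy) + r > geometry.extent_slow_mm / 2):
            raise GeometryError(
                f"zone {zone.name!r} (radius {r} mm) extends beyond the cube"
            )
    return geometry.fovea_distance_mm() <= r


def attenuated_area_mm2(percent: float, geometry: CubeGeometry) -> float:
    """Convert an en-face attenuation percentage to an absolute area.

    percent/100 of the total scan area; at the default 6 x 6 mm geometry a
    4 % attenuation corresponds to 1.44 mm^2.
    """
    if percent < 0:
        raise ValidationError("percentage must be non-negative")
    return percent / 100.0 * geometry.scan_area_mm2
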