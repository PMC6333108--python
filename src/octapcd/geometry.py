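"""Peripapillary ring and sector geometry.

Densities are measured inside an annulus bounded by two concentric circles
centred on the optic disc (defaults 1.95 mm and 3.45 mm diameter).  The inner
disk is the "disc area"; the annulus between the circles is the peripapillary
ring.  The ring is divided either into four 90-degree quadrants (superior,
nasal, inferior, temporal) or into the six Garway-Heath sextants used by
commercial peripapillary maps.

All geometry is laterality-aware: which side of the image is nasal depends on
whether the eye is a right (OD) or left (OS) eye.  The orientation convention
(row 0 = superior; nasal on the right of an OD image) is explicit and
configurable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .errors import ValidationError

DEFAULT_INNER_DIAMETER_MM = 1.95
DEFAULT_OUTER_DIAMETER_MM = 3.45

FOUR_SECTOR_LABELS = ("superior", "nasal", "inferior", "temporal")
SIX_SECTOR_LABELS = (
    "temporal",
    "superotemporal",
    "superonasal",
    "nasal",
    "inferonasal",
    "inferotemporal",
)

# Angular extents in degrees, measured anatomically: 0 deg = temporal
# horizontal meridian, increasing towards superior.  Half-open [lo, hi).
_FOUR_SECTOR_ANGLES = {
    "superior": (45.0, 135.0),
    "nasal": (135.0, 225.0),
    "inferior": (225.0, 315.0),
    "temporal": (315.0, 405.0),  # wraps through 0
}
# Garway-Heath sextants (temporal 311-41, nasal 121-231, others 40 deg).
_SIX_SECTOR_ANGLES = {
    "temporal": (311.0, 401.0),  # wraps through 0
    "superotemporal": (41.0, 81.0),
    "superonasal": (81.0, 121.0),
    "nasal": (121.0, 231.0),
    "inferonasal": (231.0, 271.0),
    "inferotemporal": (271.0, 311.0),
}


@dataclass(frozen=True)
class RingGeometry:
    """Pixel geometry of the disc disk and peripapillary annulus.

    Attributes
    ----------
    disc_center_px : (row, col) of the disc centre in pixel coordinates.
    inner_diameter_mm, outer_diameter_mm : circle diameters in millimetres.
    scale_um_per_px : physical pixel pitch.
    image_shape : (rows, cols) of the pixel grid.
    laterality : "OD" or "OS".
    nasal_right_for_od : orientation convention; if True the nasal side of an
        OD image is the right half (and mirrored for OS).
    """

    disc_center_px: Tuple[float, float]
    scale_um_per_px: float
    image_shape: Tuple[int, int]
    inner_diameter_mm: float = DEFAULT_INNER_DIAMETER_MM
    outer_diameter_mm: float = DEFAULT_OUTER_DIAMETER_MM
    laterality: str = "OD"
    nasal_right_for_od: bool = True
    _radius_px: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.scale_um_per_px <= 0:
            raise ValidationError("scale_um_per_px must be positive")
        if self.inner_diameter_mm <= 0:
            raise ValidationError("inner_diameter_mm must be positive")
        if self.inner_diameter_mm >= self.outer_diameter_mm:
            raise ValidationError(
                "inner_diameter_mm must be strictly smaller than outer_diameter_mm"
            )
        if self.laterality not in ("OD", "OS"):
            raise ValidationError("laterality must be 'OD' or 'OS'")
        rows, cols = self.image_shape
        rr, cc = np.ogrid[0:rows, 0:cols]
        r = np.hypot(rr - self.disc_center_px[0], cc - self.disc_center_px[1])
        object.__setattr__(self, "_radius_px", r * self.scale_um_per_px / 1000.0)

    # --- masks -----------------------------------------------------------
    @property
    def disc_mask(self) -> np.ndarray:
        """Inner disk ('disc area'), radius = inner diameter / 2."""
        return self._radius_px <= self.inner_diameter_mm / 2.0

    @property
    def outer_disk_mask(self) -> np.ndarray:
        return self._radius_px <= self.outer_diameter_mm / 2.0

    @property
    def annulus_mask(self) -> np.ndarray:
        """Peripapillary ring: outer disk minus inner disk (exact set difference)."""
        return self.outer_disk_mask & ~self.disc_mask

    @property
    def whole_image_mask(self) -> np.ndarray:
        return np.ones(self.image_shape, dtype=bool)

    # --- areas -----------------------------------------------------------
    @property
    def pixel_area_mm2(self) -> float:
        return (self.scale_um_per_px / 1000.0) ** 2

    def area_mm2(self, mask: np.ndarray) -> float:
        return float(np.count_nonzero(mask)) * self.pixel_area_mm2

    def anatomical_angle_deg(self) -> np.ndarray:
        """Per-pixel anatomical angle in [0, 360).

        0 deg points along the temporal horizontal meridian and the angle
        increases towards superior, so superior = 90, nasal = 180,
        inferior = 270 regardless of laterality.
        """
        rows, cols = self.image_shape
        rr, cc = np.ogrid[0:rows, 0:cols]
        up = -(rr - self.disc_center_px[0])  # row 0 is superior
        dx = cc - self.disc_center_px[1]
        nasal_right = self.nasal_right_for_od if self.laterality == "OD" else not self.nasal_right_for_od
        temporal = -dx if nasal_right else dx
        ang = np.degrees(np.arctan2(up, temporal))
        return np.mod(ang, 360.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "disc_center_px": list(self.disc_center_px),
                "inner_diameter_mm": self.inner_diameter_mm,
                "outer_diameter_mm": self.outer_diameter_mm,
                "scale_um_per_px": self.scale_um_per_px,
                "image_shape": list(self.image_shape),
                "laterality": self.laterality,
                "orientation": {
                    "row0": "superior",
                    "nasal_right_for_od": self.nasal_right_for_od,
                },
            }
        )


@dataclass(frozen=True)
class SectorMap:
    """Partition of the annulus into named sectors.

    ``masks[label]`` is a boolean image; the masks are pairwise disjoint and
    their union is exactly the annulus.
    """

    scheme: str
    masks: Dict[str, np.ndarray]
    laterality: str

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(self.masks.keys())


def build_rings(
    center_px: Tuple[float, float],
    inner_mm: float,
    outer_mm: float,
    scale_um_per_px: float,
    image_shape: Tuple[int, int],
    laterality: str = "OD",
    nasal_right_for_od: bool = True,
) -> RingGeometry:
    """Construct the ring geometry, warning if the outer circle is clipped."""
    rings = RingGeometry(
        disc_center_px=tuple(center_px),
        scale_um_per_px=scale_um_per_px,
        image_shape=tuple(image_shape),
        inner_diameter_mm=inner_mm,
        outer_diameter_mm=outer_mm,
        laterality=laterality,
        nasal_right_for_od=nasal_right_for_od,
    )
    r_px = outer_mm / 2.0 * 1000.0 / scale_um_per_px
    rows, cols = image_shape
    cr, cc = center_px
    if cr - r_px < -0.5 or cc - r_px < -0.5 or cr + r_px > rows - 0.5 or cc + r_px > cols - 0.5:
        warnings.warn(
            "outer circle extends beyond the image; annulus is clipped",
            stacklevel=2,
        )
    return rings


def build_sectors(rings: RingGeometry, scheme: str) -> SectorMap:
    """Split the annulus into the four-quadrant or six-sextant map.

    four_sector: quadrants bounded by the +-45 degree diagonals through the
    disc centre.  six_sector: Garway-Heath sextants.  Sector naming is
    anatomical, so the nasal/temporal pixel sets mirror between OD and OS.
    """
    if scheme == "four_sector":
        table = _FOUR_SECTOR_ANGLES
        order = FOUR_SECTOR_LABELS
    elif scheme == "six_sector":
        table = _SIX_SECTOR_ANGLES
        order = SIX_SECTOR_LABELS
    else:
        raise ValidationError(f"unknown sector scheme: {scheme!r}")

    ann = rings.annulus_mask
    ang = rings.anatomical_angle_deg()
    masks = {}
    for label in order:
        lo, hi = table[label]
        if hi > 360.0:  # wraps through the temporal meridian
            sel = (ang >= lo) | (ang < hi - 360.0)
        else:
            sel = (ang >= lo) & (ang < hi)
        masks[label] = ann & sel
    return SectorMap(scheme=scheme, masks=masks, laterality=rings.laterality)
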