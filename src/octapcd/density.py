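"""Vessel/capillary density metrics for one eye and slab.

Two measurement modes are produced for every eye:

* ``commercial_style`` — total vascular density: the fraction of perfused
  pixels (capillaries *and* large vessels) in a region, reported for the
  whole peripapillary ring and its six Garway-Heath sextants.  This emulates
  the density maps commercial OCT-A software prints.
* ``custom_capillary`` — capillary density after large-vessel removal:
  whole-image density (full frame, disc included), whole peripapillary
  capillary density (PCD; the 1.95–3.45 mm annulus, disc excluded), and the
  four ring quadrants.

Densities are pixel-count ratios expressed in percent.  With the default
``include_large`` denominator convention, removed large-vessel pixels stay in
the denominator as non-capillary tissue; ``exclude_large`` drops them from
the denominator as well (sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import EmptyRegionError, ValidationError
from .geometry import RingGeometry, SectorMap, build_rings, build_sectors
from .segmentation import (
    Angiogram,
    VesselMaskSet,
    binarize,
    remove_large_vessels,
    DEFAULT_CALIBER_CUTOFF_UM,
)

MODES = ("commercial_style", "custom_capillary")
CONVENTIONS = ("include_large", "exclude_large")


@dataclass
class DensityReport:
    """All density metrics for one eye/slab in one mode.

    ``sector_densities`` maps sector label -> percent; ``sector_weights``
    carries the denominator pixel counts actually used, so the area-weighted
    mean of the sector densities reproduces ``whole_pcd`` exactly.
    Values are stored at full precision; display rounds to 0.1%.
    """

    slab: str
    mode: str
    whole_image_density: float
    whole_pcd: float
    sector_densities: Dict[str, float]
    sector_weights: Dict[str, int]
    denominator_convention: str
    provenance: Dict = field(default_factory=dict)

    def sector_weighted_mean(self) -> float:
        w = np.array([self.sector_weights[k] for k in self.sector_densities])
        d = np.array([self.sector_densities[k] for k in self.sector_densities])
        return float(np.sum(w * d) / np.sum(w))

    def to_dict(self) -> Dict:
        return {
            "slab": self.slab,
            "mode": self.mode,
            "whole_image_density": self.whole_image_density,
            "whole_pcd": self.whole_pcd,
            "sector_densities": dict(self.sector_densities),
            "sector_weights": {k: int(v) for k, v in self.sector_weights.items()},
            "denominator_convention": self.denominator_convention,
            "provenance": self.provenance,
        }

    def __str__(self) -> str:
        sectors = ", ".join(f"{k}={v:.1f}%" for k, v in self.sector_densities.items())
        return (
            f"{self.mode} ({self.slab}): whole image {self.whole_image_density:.1f}%, "
            f"whole PCD {self.whole_pcd:.1f}% [{sectors}]"
        )


def compute_density(
    masks: VesselMaskSet,
    region_mask: np.ndarray,
    mode: str = "custom_capillary",
    convention: str = "include_large",
) -> float:
    """Percent density of the relevant mask inside ``region_mask``.

    commercial_style: 100 * |perfusion ∩ region| / |region|.
    custom_capillary, include_large: 100 * |capillary ∩ region| / |region|.
    custom_capillary, exclude_large: 100 * |capillary ∩ region| / |region \\ large|.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    if convention not in CONVENTIONS:
        raise ValidationError(f"convention must be one of {CONVENTIONS}")
    region = np.asarray(region_mask, dtype=bool)
    if region.shape != masks.perfusion_mask.shape:
        raise ValidationError("region_mask must match the mask grid shape")
    n_region = int(np.count_nonzero(region))
    if n_region == 0:
        raise EmptyRegionError("density over an empty region is undefined")

    if mode == "commercial_style":
        num = np.count_nonzero(masks.perfusion_mask & region)
        den = n_region
    else:
        num = np.count_nonzero(masks.capillary_mask & region)
        if convention == "include_large":
            den = n_region
        else:
            den = np.count_nonzero(region & ~masks.large_vessel_mask)
            if den == 0:
                raise EmptyRegionError(
                    "region is entirely large vessel; exclude_large density undefined"
                )
    return 100.0 * num / den


def _region_report(
    masks: VesselMaskSet,
    rings: RingGeometry,
    sectors: SectorMap,
    slab: str,
    mode: str,
    convention: str,
    provenance: Dict,
) -> DensityReport:
    whole_image = compute_density(masks, rings.whole_image_mask, mode, convention)
    whole_pcd = compute_density(masks, rings.annulus_mask, mode, convention)
    sector_densities = {}
    sector_weights = {}
    for label, sector_mask in sectors.masks.items():
        sector_densities[label] = compute_density(masks, sector_mask, mode, convention)
        if mode == "custom_capillary" and convention == "exclude_large":
            sector_weights[label] = int(
                np.count_nonzero(sector_mask & ~masks.large_vessel_mask)
            )
        else:
            sector_weights[label] = int(np.count_nonzero(sector_mask))
    return DensityReport(
        slab=slab,
        mode=mode,
        whole_image_density=whole_image,
        whole_pcd=whole_pcd,
        sector_densities=sector_densities,
        sector_weights=sector_weights,
        denominator_convention=convention,
        provenance=provenance,
    )


def measure_eye(
    image: Angiogram,
    rings: Optional[RingGeometry] = None,
    caliber_cutoff_um: float = DEFAULT_CALIBER_CUTOFF_UM,
    convention: str = "include_large",
    threshold_method: str = "local_mean",
    rim_dilation_px: int = 1,
    enforce_quality: bool = True,
) -> Tuple[DensityReport, DensityReport]:
    """Run the full per-eye measurement and return both density reports.

    Returns ``(commercial_style, custom_capillary)``.  The commercial-style
    report uses the raw perfusion mask with the six-sextant map; the custom
    report removes large vessels first and uses the four-quadrant map.  If no
    ring geometry is supplied, the rings are centred on the image.
    """
    if rings is None:
        rows, cols = image.shape
        rings = build_rings(
            ((rows - 1) / 2.0, (cols - 1) / 2.0),
            1.95,
            3.45,
            image.scale_um_per_px,
            image.shape,
            laterality=image.laterality,
        )
    masks = binarize(image, method=threshold_method, enforce_quality=enforce_quality)
    masks = remove_large_vessels(
        masks, caliber_cutoff_um=caliber_cutoff_um, rim_dilation_px=rim_dilation_px
    )
    provenance = dict(masks.provenance)
    provenance["threshold_value"] = masks.threshold_value

    six = build_sectors(rings, "six_sector")
    four = build_sectors(rings, "four_sector")
    commercial = _region_report(
        masks, rings, six, image.slab, "commercial_style", "include_large", provenance
    )
    custom = _region_report(
        masks, rings, four, image.slab, "custom_capillary", convention, provenance
    )
    return commercial, custom
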