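"""Synthetic angiograms with known ground truth, and synthetic cohort tables.

No raw images or per-eye tables are distributed with the study this package
reanalyses, so everything downstream is exercised on synthetic data:

* :func:`generate_angiogram` draws an en-face peripapillary angiogram —
  a branching large-vessel tree radiating from the optic disc, a capillary
  plexus at a known perfusion fraction, a signal-free disc interior, and
  additive speckle noise — and returns the ground-truth masks alongside.
* :func:`generate_cohort` draws long-format per-eye measurement tables with
  the reported per-group means/SDs and a per-subject random intercept that
  induces the two-eye (intereye) correlation the statistics layer must
  account for.

The capillary plexus is drawn as a soup of thin curvilinear strands and then
thinned so that **every capillary pixel retains a 4-connected background
neighbour**.  On the pixel grid this bounds the capillary caliber at
``2 * scale_um_per_px`` (29.6 um at the default 14.8 um/px pitch), strictly
below the large-vessel caliber cutoff, so the ground-truth classes are
separable by construction.  Large vessels keep a 2-px capillary-free
clearance zone (the periarteriolar capillary-free zone seen in real
angiograms), so vessel-rim handling in segmentation cannot absorb
ground-truth capillary pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from skimage.morphology import dilation, disk

from . import reference
from .errors import AchievabilityError, ValidationError
from .geometry import build_rings
from .segmentation import Angiogram, DEFAULT_CALIBER_CUTOFF_UM

# Noise-free intensity levels (dynamic range [0, 1]).
BACKGROUND_LEVEL = 0.08
CAPILLARY_LEVEL = 0.75
VESSEL_LEVEL = 1.0

#: Practical ceiling on the achievable capillary fraction under the
#: caliber-separability constraint (see module docstring).
MAX_CAPILLARY_FRACTION = 0.60

_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class AngiogramSpec:
    """Parameters of one synthetic angiogram.

    The defaults emulate the study's acquisition: a 4.5 x 4.5 mm scan
    centred on the optic disc, rasterised at 304 x 304 px (a common
    commercial OCT-A raster; the physical pitch is
    ``field_mm * 1000 / image_px`` = 14.8 um/px).
    """

    field_mm: float = 4.5
    image_px: int = 304
    disc_center_frac: Tuple[float, float] = (0.5, 0.5)
    disc_radius_mm: float = 0.975
    capillary_fraction_target: float = 0.35
    n_large_vessels: int = 8
    large_vessel_width_um_range: Tuple[float, float] = (60.0, 120.0)
    noise_sd: float = 0.05
    ssi: float = 65.0
    laterality: str = "OD"
    slab: str = "irVD"
    seed: int = 0
    #: Caliber cutoff the segmentation stage will use; the generator keeps
    #: capillary calibers strictly below it and vessel calibers above it.
    separability_cutoff_um: float = DEFAULT_CALIBER_CUTOFF_UM

    @property
    def scale_um_per_px(self) -> float:
        return self.field_mm * 1000.0 / self.image_px

    def validate(self) -> None:
        if self.image_px <= 0:
            raise ValidationError("image_px must be positive")
        if self.field_mm <= 0:
            raise ValidationError("field_mm must be positive")
        if not 0.0 <= self.capillary_fraction_target <= 1.0:
            raise ValidationError("capillary_fraction_target must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_large_vessels < 0:
            raise ValidationError("n_large_vessels must be >= 0")
        if self.disc_radius_mm < 0:
            raise ValidationError("disc_radius_mm must be >= 0")
        wmin, wmax = self.large_vessel_width_um_range
        if not 0 < wmin <= wmax:
            raise ValidationError("large_vessel_width_um_range must satisfy 0 < min <= max")
        if self.n_large_vessels > 0 and wmin <= self.separability_cutoff_um:
            raise ValidationError(
                "large_vessel_width_um_range minimum must be strictly greater than "
                "separability_cutoff_um, otherwise ground-truth classes are not separable"
            )
        if 2.0 * self.scale_um_per_px >= self.separability_cutoff_um:
            raise ValidationError(
                "scale_um_per_px too coarse: single-pixel capillary caliber "
                "(2 x pitch) must stay below separability_cutoff_um"
            )
        if self.laterality not in ("OD", "OS"):
            raise ValidationError("laterality must be 'OD' or 'OS'")


@dataclass
class GroundTruth:
    """Ground-truth masks and densities for one synthetic angiogram.

    The capillary and large-vessel masks are disjoint; the stored densities
    are recomputable from the masks by pixel counting.
    ``true_capillary_density_annulus`` uses the default 1.95/3.45 mm ring
    with the full annulus as denominator.
    """

    capillary_mask: np.ndarray
    large_vessel_mask: np.ndarray
    disc_mask: np.ndarray
    true_capillary_density_whole: float
    true_capillary_density_annulus: float

    def recompute_densities(self, annulus_mask: np.ndarray) -> Tuple[float, float]:
        whole = 100.0 * self.capillary_mask.sum() / self.capillary_mask.size
        ann = 100.0 * (self.capillary_mask & annulus_mask).sum() / annulus_mask.sum()
        return float(whole), float(ann)


# --------------------------------------------------------------------------
# angiogram generation internals
# --------------------------------------------------------------------------

def _draw_vessel_tree(spec: AngiogramSpec, rng: np.random.Generator) -> np.ndarray:
    """Stroke a branching tree of random-walk polylines from the disc centre."""
    n = spec.image_px
    scale = spec.scale_um_per_px
    center = (spec.disc_center_frac[0] * (n - 1), spec.disc_center_frac[1] * (n - 1))
    max_steps = int(n * 1.6)
    wmin, wmax = spec.large_vessel_width_um_range

    # centreline pixels grouped by stroke radius (px)
    by_radius: Dict[int, List[np.ndarray]] = {}
    jobs = []  # (start_row, start_col, heading, width_um)
    for i in range(spec.n_large_vessels):
        heading = rng.uniform(0, 2 * math.pi)
        jobs.append((center[0], center[1], heading, rng.uniform(wmin, wmax)))

    vessel = np.zeros((n, n), dtype=bool)
    while jobs:
        r0, c0, heading, width_um = jobs.pop()
        turns = rng.normal(0.0, 0.10, size=max_steps)
        theta = heading + np.cumsum(turns)
        rows = r0 + np.cumsum(np.sin(theta))
        cols = c0 + np.cumsum(np.cos(theta))
        ri = np.round(rows).astype(int)
        ci = np.round(cols).astype(int)
        inside = (ri >= 0) & (ri < n) & (ci >= 0) & (ci < n)
        if inside.any():
            stop = int(np.argmin(inside)) if not inside.all() else max_steps
            rows, cols = rows[:stop], cols[:stop]
            radius = max(1, int(round(width_um / 2.0 / scale)))
            by_radius.setdefault(radius, []).append(np.stack([ri[:stop], ci[:stop]]))
            # occasional branch, same caliber family
            if len(rows) > 20 and rng.random() < 0.5 and len(jobs) < 4 * spec.n_large_vessels:
                k = rng.integers(10, len(rows))
                jobs.append(
                    (
                        rows[k],
                        cols[k],
                        theta[k] + rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 0.9),
                        rng.uniform(wmin, wmax),
                    )
                )
    for radius, point_sets in by_radius.items():
        line = np.zeros((n, n), dtype=bool)
        for pts in point_sets:
            line[pts[0], pts[1]] = True
        vessel |= dilation(line, disk(radius))
    return vessel


def _neighbour_bg_count(solid: np.ndarray) -> np.ndarray:
    """Per-pixel count of 4-neighbours that are background.

    Outside the image counts as solid, matching the semantics of the
    Euclidean distance transform the segmentation stage uses (which only
    sees background inside the array).
    """
    pad = np.pad(solid, 1, constant_values=True).astype(np.int8)
    nb = pad[:-2, 1:-1] + pad[2:, 1:-1] + pad[1:-1, :-2] + pad[1:-1, 2:]
    return (4 - nb).astype(np.int16)


def _thin_to_breathing(capillary: np.ndarray, solid: np.ndarray, rng) -> None:
    """Sequentially delete capillary pixels whose 4-neighbourhood is solid.

    After this, every capillary pixel has a background 4-neighbour, i.e.
    EDT == 1 exactly; removals are processed in random order with rechecks,
    so no pixel is deleted whose neighbourhood was already vented by an
    earlier deletion.  Mutates ``capillary`` and ``solid`` in place.
    """
    bgn = _neighbour_bg_count(solid)
    viol = np.argwhere(capillary & (bgn == 0))
    if len(viol) == 0:
        return
    order = rng.permutation(len(viol))
    nrows, ncols = solid.shape
    for idx in order:
        r, c = int(viol[idx, 0]), int(viol[idx, 1])
        if bgn[r, c] != 0 or not capillary[r, c]:
            continue
        capillary[r, c] = False
        solid[r, c] = False
        for dr, dc in _N4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols:
                bgn[rr, cc] += 1


def _strand_batch(
    rng: np.random.Generator,
    n_strands: int,
    length: int,
    allowed: np.ndarray,
) -> Optional[np.ndarray]:
    """Pixel mask of ``n_strands`` jittered random-walk strands in ``allowed``."""
    starts = np.argwhere(allowed)
    if len(starts) == 0 or n_strands <= 0:
        return None
    pick = starts[rng.integers(0, len(starts), size=n_strands)]
    theta0 = rng.uniform(0, 2 * math.pi, size=n_strands)
    turns = rng.normal(0.0, 0.35, size=(n_strands, length))
    theta = theta0[:, None] + np.cumsum(turns, axis=1)
    rows = pick[:, 0, None] + np.cumsum(np.sin(theta), axis=1)
    cols = pick[:, 1, None] + np.cumsum(np.cos(theta), axis=1)
    r = np.round(rows).astype(int).ravel()
    c = np.round(cols).astype(int).ravel()
    nrows, ncols = allowed.shape
    ok = (r >= 0) & (r < nrows) & (c >= 0) & (c < ncols)
    r, c = r[ok], c[ok]
    mask = np.zeros_like(allowed)
    mask[r, c] = True
    return mask & allowed


def _fill_capillaries(
    spec: AngiogramSpec,
    vessel: np.ndarray,
    disc: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw the capillary plexus at the exact target pixel count."""
    clearance = dilation(vessel, disk(2)) if vessel.any() else vessel
    allowed = ~disc & ~clearance
    denominator = ~disc & ~vessel  # target fraction is of the non-large-vessel area
    target = int(round(spec.capillary_fraction_target * np.count_nonzero(denominator)))
    capillary = np.zeros_like(vessel)
    if target == 0:
        return capillary
    if spec.capillary_fraction_target > MAX_CAPILLARY_FRACTION:
        raise AchievabilityError(
            "capillary_fraction_target above the achievable ceiling "
            f"({MAX_CAPILLARY_FRACTION}) under the caliber-separability constraint"
        )

    solid = vessel.copy()
    strand_len = 40
    stalled = 0
    for _ in range(60):
        count = int(np.count_nonzero(capillary))
        if count >= target:
            break
        deficit = target - count
        n_strands = max(8, int(1.4 * deficit / strand_len))
        batch = _strand_batch(rng, n_strands, strand_len, allowed)
        if batch is None:
            break
        capillary |= batch
        solid = vessel | capillary
        _thin_to_breathing(capillary, solid, rng)
        new_count = int(np.count_nonzero(capillary))
        if new_count <= count:
            stalled += 1
            if stalled >= 5:
                raise AchievabilityError(
                    "capillary fill stalled at fraction "
                    f"{count / np.count_nonzero(denominator):.3f} "
                    f"(target {spec.capillary_fraction_target})"
                )
        else:
            stalled = 0
    count = int(np.count_nonzero(capillary))
    if count < target:
        raise AchievabilityError(
            f"could not reach capillary_fraction_target={spec.capillary_fraction_target}"
        )
    if count > target:  # trim random excess; removal never breaks the constraint
        rr, cc = np.nonzero(capillary)
        drop = rng.choice(len(rr), size=count - target, replace=False)
        capillary[rr[drop], cc[drop]] = False
    return capillary


def generate_angiogram(spec: AngiogramSpec) -> Tuple[Angiogram, GroundTruth]:
    """Render one synthetic angiogram and its ground truth.

    Deterministic for a fixed ``spec.seed``; all randomness flows through a
    local generator (no global RNG state is touched).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_px
    center = (spec.disc_center_frac[0] * (n - 1), spec.disc_center_frac[1] * (n - 1))

    rr, cc = np.ogrid[0:n, 0:n]
    radius_px = spec.disc_radius_mm * 1000.0 / spec.scale_um_per_px
    disc = np.hypot(rr - center[0], cc - center[1]) <= radius_px

    vessel = (
        _draw_vessel_tree(spec, rng)
        if spec.n_large_vessels > 0
        else np.zeros((n, n), dtype=bool)
    )
    capillary = _fill_capillaries(spec, vessel, disc, rng)

    img = np.full((n, n), BACKGROUND_LEVEL, dtype=float)
    img[capillary] = CAPILLARY_LEVEL
    img[vessel] = VESSEL_LEVEL
    if spec.noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, spec.noise_sd, size=img.shape), 0.0, 1.0)

    angiogram = Angiogram(
        pixels=img,
        scale_um_per_px=spec.scale_um_per_px,
        laterality=spec.laterality,
        slab=spec.slab,
        ssi=spec.ssi,
    )
    rings = build_rings(
        center, 1.95, 3.45, spec.scale_um_per_px, (n, n), laterality=spec.laterality
    )
    annulus = rings.annulus_mask
    gt = GroundTruth(
        capillary_mask=capillary,
        large_vessel_mask=vessel,
        disc_mask=disc,
        true_capillary_density_whole=100.0 * capillary.sum() / capillary.size,
        true_capillary_density_annulus=100.0 * (capillary & annulus).sum() / annulus.sum(),
    )
    return angiogram, gt


# --------------------------------------------------------------------------
# cohort tables
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Distributional specification of a synthetic per-eye cohort table.

    groups : list of ``(name, n_subjects, n_eyes_total)``; eyes beyond one
        per subject are distributed as second eyes (at most two per subject).
    metric_params : ``metric -> group -> (mean, sd)`` of the per-eye values.
    subject_sd : SD of the per-subject random intercept; either one value
        for all metrics or ``metric -> sd``.  Must be strictly below every
        group's metric SD (the residual SD is ``sqrt(sd^2 - subject_sd^2)``).
    """

    groups: Sequence[Tuple[str, int, int]]
    metric_params: Dict[str, Dict[str, Tuple[float, float]]]
    subject_sd: Union[float, Dict[str, float]] = 0.0
    ssi_mean: float = 65.0
    ssi_sd: float = 6.0
    seed: int = 0

    def subject_sd_for(self, metric: str) -> float:
        if isinstance(self.subject_sd, dict):
            return float(self.subject_sd.get(metric, 0.0))
        return float(self.subject_sd)

    def validate(self) -> None:
        for name, n_subjects, n_eyes in self.groups:
            if n_subjects <= 0:
                raise ValidationError(f"group {name!r}: n_subjects must be positive")
            if not n_subjects <= n_eyes <= 2 * n_subjects:
                raise ValidationError(
                    f"group {name!r}: n_eyes must allow 1-2 eyes per subject"
                )
        for metric, per_group in self.metric_params.items():
            tau = self.subject_sd_for(metric)
            for name, _, _ in self.groups:
                if name not in per_group:
                    raise ValidationError(
                        f"metric_params[{metric!r}] missing group {name!r}"
                    )
                _, sd = per_group[name]
                if sd <= 0:
                    raise ValidationError(f"metric_params[{metric!r}][{name!r}]: sd must be > 0")
                if tau >= sd:
                    raise ValidationError(
                        f"subject_sd for {metric!r} must be strictly below the "
                        f"metric sd of group {name!r}"
                    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a long-format per-eye cohort table.

    Each eye's value is ``group mean + subject intercept + residual`` with
    ``intercept ~ N(0, subject_sd)`` and
    ``residual ~ N(0, sqrt(sd^2 - subject_sd^2))``, so the marginal per-eye
    SD equals the requested ``sd`` and two eyes of one subject correlate at
    ``subject_sd^2 / sd^2``.

    Columns: ``subject_id, eye, group, metric, value, ssi``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records = []
    for name, n_subjects, n_eyes in spec.groups:
        n_second = n_eyes - n_subjects
        eyes_per_subject = [2] * n_second + [1] * (n_subjects - n_second)
        subject_ids = [f"{name}_{i:03d}" for i in range(n_subjects)]
        ssi_by_eye = {}
        for sid, k in zip(subject_ids, eyes_per_subject):
            for eye in (["OD", "OS"][:k]):
                ssi_by_eye[(sid, eye)] = float(rng.normal(spec.ssi_mean, spec.ssi_sd))
        for metric, per_group in spec.metric_params.items():
            mean, sd = per_group[name]
            tau = spec.subject_sd_for(metric)
            resid_sd = math.sqrt(sd**2 - tau**2)
            intercepts = rng.normal(0.0, tau, size=n_subjects) if tau > 0 else np.zeros(n_subjects)
            for sid, k, b in zip(subject_ids, eyes_per_subject, intercepts):
                for eye in (["OD", "OS"][:k]):
                    records.append(
                        {
                            "subject_id": sid,
                            "eye": eye,
                            "group": name,
                            "metric": metric,
                            "value": mean + b + rng.normal(0.0, resid_sd),
                            "ssi": ssi_by_eye[(sid, eye)],
                        }
                    )
    return pd.DataFrame.from_records(
        records, columns=["subject_id", "eye", "group", "metric", "value", "ssi"]
    )


def default_cohort_spec(seed: int = 0, icc: float = 0.5) -> CohortSpec:
    """Cohort spec with the published group sizes and summary statistics.

    ``icc`` sets the intereye correlation via a per-metric subject SD of
    ``sqrt(icc) * min-group SD`` (the intercept SD must sit below every
    group's marginal SD).
    """
    groups = [
        (name, n_subjects, n_eyes)
        for name, (n_subjects, n_eyes) in reference.GROUP_SIZES.items()
    ]
    subject_sd = {
        metric: math.sqrt(icc) * min(sd for _, sd in per_group.values())
        for metric, per_group in reference.GROUP_SUMMARIES.items()
    }
    return CohortSpec(
        groups=groups,
        metric_params={m: dict(v) for m, v in reference.GROUP_SUMMARIES.items()},
        subject_sd=subject_sd,
        seed=seed,
    )
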