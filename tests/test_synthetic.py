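"""Synthetic angiogram and cohort generators: ground-truth guarantees."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from octapcd.errors import ValidationError
from octapcd.geometry import build_rings
from octapcd.synthetic import (
    AngiogramSpec,
    CohortSpec,
    default_cohort_spec,
    generate_angiogram,
    generate_cohort,
)


class TestGenerateAngiogram:
    def test_empty_spec_gives_constant_background(self):
        spec = AngiogramSpec(
            capillary_fraction_target=0.0, n_large_vessels=0, noise_sd=0.0, seed=0
        )
        image, gt = generate_angiogram(spec)
        assert np.ptp(image.pixels) == 0
        assert not gt.capillary_mask.any()
        assert not gt.large_vessel_mask.any()

    @pytest.mark.parametrize("fraction", [0.15, 0.35, 0.50])
    def test_capillary_fraction_is_exact(self, fraction):
        """Capillary pixel count over the non-disc area hits the target exactly
        (no vessels, so the denominator is simply everything outside the disc)."""
        spec = AngiogramSpec(
            capillary_fraction_target=fraction, n_large_vessels=0, noise_sd=0.0, seed=5
        )
        _, gt = generate_angiogram(spec)
        denom = np.count_nonzero(~gt.disc_mask)
        achieved = gt.capillary_mask.sum() / denom
        assert achieved == pytest.approx(fraction, abs=1.0 / denom)

    def test_deterministic_for_fixed_seed(self):
        spec = AngiogramSpec(capillary_fraction_target=0.3, seed=42)
        a1, g1 = generate_angiogram(spec)
        a2, g2 = generate_angiogram(AngiogramSpec(capillary_fraction_target=0.3, seed=42))
        assert np.array_equal(a1.pixels, a2.pixels)
        assert np.array_equal(g1.capillary_mask, g2.capillary_mask)

    def test_masks_disjoint_and_densities_recomputable(self, default_angiogram):
        _, gt = default_angiogram
        assert not np.any(gt.capillary_mask & gt.large_vessel_mask)
        spec = AngiogramSpec()
        n = spec.image_px
        rings = build_rings(
            ((n - 1) / 2, (n - 1) / 2), 1.95, 3.45, spec.scale_um_per_px, (n, n)
        )
        whole, annulus = gt.recompute_densities(rings.annulus_mask)
        assert whole == pytest.approx(gt.true_capillary_density_whole, abs=1e-9)
        assert annulus == pytest.approx(gt.true_capillary_density_annulus, abs=1e-9)

    def test_capillary_caliber_stays_below_cutoff(self, default_angiogram):
        """Every capillary pixel keeps EDT == 1 in the solid union, so its
        discrete caliber (2 * EDT * pitch = 29.6 um) is below the 32 um
        large-vessel cutoff: the ground-truth classes are separable."""
        _, gt = default_angiogram
        solid = gt.capillary_mask | gt.large_vessel_mask
        edt = ndi.distance_transform_edt(solid)
        assert edt[gt.capillary_mask].max() == 1.0

    def test_disc_interior_carries_no_capillary(self, default_angiogram):
        _, gt = default_angiogram
        assert not np.any(gt.capillary_mask & gt.disc_mask)

    def test_large_vessels_have_cutoff_exceeding_caliber(self, default_angiogram):
        _, gt = default_angiogram
        edt = ndi.distance_transform_edt(gt.large_vessel_mask)
        spec = AngiogramSpec()
        # the widest point of every trunk must exceed the separability cutoff
        assert 2 * edt.max() * spec.scale_um_per_px > spec.separability_cutoff_um

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"capillary_fraction_target": 1.2}, "capillary_fraction_target"),
            ({"image_px": 0}, "image_px"),
            ({"noise_sd": -0.1}, "noise_sd"),
            ({"large_vessel_width_um_range": (20.0, 120.0)}, "large_vessel_width_um_range"),
            ({"laterality": "XX"}, "laterality"),
        ],
    )
    def test_invalid_spec_names_field(self, kwargs, field):
        with pytest.raises(ValidationError, match=field.split("_")[0]):
            generate_angiogram(AngiogramSpec(**kwargs))


class TestGenerateCohort:
    def test_row_count_matches_eyes(self):
        spec = CohortSpec(
            groups=[("control", 44, 44)],
            metric_params={"m": {"control": (10.0, 2.0)}},
            subject_sd=1.0,
            seed=0,
        )
        table = generate_cohort(spec)
        assert len(table) == 44
        assert set(table.columns) >= {"subject_id", "eye", "group", "metric", "value", "ssi"}

    def test_two_eyes_capped_per_subject(self):
        spec = CohortSpec(
            groups=[("papilledema", 21, 41)],
            metric_params={"m": {"papilledema": (30.0, 9.0)}},
            subject_sd=3.0,
            seed=1,
        )
        table = generate_cohort(spec)
        per_subject = table.groupby("subject_id").size()
        assert len(table) == 41
        assert per_subject.max() == 2

    def test_group_mean_and_sd_converge(self):
        """Empirical mean/SD approach the requested values at n = 10,000."""
        spec = CohortSpec(
            groups=[("g", 10_000, 10_000)],
            metric_params={"m": {"g": (31.8, 7.4)}},
            subject_sd=5.0,
            seed=7,
        )
        vals = generate_cohort(spec)["value"]
        assert vals.mean() == pytest.approx(31.8, rel=0.02)
        assert vals.std(ddof=1) == pytest.approx(7.4, rel=0.02)

    @pytest.mark.parametrize("icc_target", [0.0, 0.5])
    def test_intereye_correlation_matches_subject_variance_share(self, icc_target):
        """Two eyes of one subject correlate at subject_sd^2 / sd^2."""
        sd = 8.0
        spec = CohortSpec(
            groups=[("g", 5_000, 10_000)],
            metric_params={"m": {"g": (30.0, sd)}},
            subject_sd=np.sqrt(icc_target) * sd,
            seed=3,
        )
        table = generate_cohort(spec)
        wide = table.pivot(index="subject_id", columns="eye", values="value").dropna()
        r = np.corrcoef(wide["OD"], wide["OS"])[0, 1]
        assert r == pytest.approx(icc_target, abs=0.05)

    def test_subject_sd_must_stay_below_metric_sd(self):
        spec = CohortSpec(
            groups=[("g", 5, 5)],
            metric_params={"m": {"g": (10.0, 2.0)}},
            subject_sd=2.0,
        )
        with pytest.raises(ValidationError, match="subject_sd"):
            generate_cohort(spec)

    def test_default_spec_covers_published_groups(self):
        table = generate_cohort(default_cohort_spec(seed=0))
        counts = (
            table[table["metric"] == "rnfl_average_um"].groupby("group").size().to_dict()
        )
        assert counts == {"papilledema": 41, "pseudopapilledema": 27, "control": 44}
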