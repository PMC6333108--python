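"""End-to-end driver: simulate angiograms, measure densities, run statistics.

``run_pipeline`` produces a deterministic artifact directory::

    images/   synthetic angiograms (PNG + JSON sidecar)
    masks/    ground-truth and measured masks (PNG)
    reports/  per-eye density reports (JSON)
    tables/   long-format cohort table (CSV)
    stats/    group contrasts (CSV), agreement and ROC results (JSON)
    run.log   deterministic processing log (thresholds, exclusions)
    manifest.json  config echo + SHA-256 of every artifact

All randomness flows from the config seed, so identical configs give
bit-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .density import measure_eye
from .errors import QualityGateError, UndefinedStatisticError, ValidationError
from .geometry import build_rings
from .io_utils import write_angiogram, write_mask
from .stats import bland_altman, compare_groups, quality_disagreement_correlation, roc_analysis
from .synthetic import AngiogramSpec, generate_angiogram

_CUSTOM_SECTORS = ("superior", "nasal", "inferior", "temporal")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _rows_for_eye(subject_id, eye, group, ssi, commercial, custom) -> List[Dict]:
    rows = []

    def add(metric, value):
        rows.append(
            {
                "subject_id": subject_id,
                "eye": eye,
                "group": group,
                "metric": metric,
                "value": value,
                "ssi": ssi,
            }
        )

    add("capillary_whole_image", custom.whole_image_density)
    add("pcd_whole", custom.whole_pcd)
    for label, value in custom.sector_densities.items():
        add(f"pcd_{label}", value)
    add("commercial_whole", commercial.whole_pcd)
    for label, value in commercial.sector_densities.items():
        add(f"commercial_{label}", value)
    return rows


def run_pipeline(config: PipelineConfig, out_dir) -> Dict:
    """Run simulate → measure → analyze and return the manifest."""
    out = Path(out_dir)
    for sub in ("images", "masks", "reports", "tables", "stats"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    log_lines: List[str] = []

    master = np.random.default_rng(config.seed)
    rows: List[Dict] = []
    paired: List[Tuple[str, float, float, float]] = []  # (eye_id, custom, commercial, ssi)
    exclusions: Dict[str, int] = {}

    sim = config.simulate
    for gcfg in sim.groups:
        n_second = gcfg.n_eyes - gcfg.n_subjects
        if not 0 <= n_second <= gcfg.n_subjects:
            raise ValidationError(f"group {gcfg.name!r}: n_eyes must allow 1-2 eyes per subject")
        for s in range(gcfg.n_subjects):
            subject_id = f"{gcfg.name}_{s:03d}"
            intercept = master.normal(0.0, gcfg.capillary_fraction_subject_sd)
            eyes = ["OD", "OS"] if s < n_second else ["OD"]
            for eye in eyes:
                resid_sd = max(
                    0.0,
                    gcfg.capillary_fraction_sd**2 - gcfg.capillary_fraction_subject_sd**2,
                ) ** 0.5
                frac = float(
                    np.clip(
                        gcfg.capillary_fraction_mean + intercept + master.normal(0.0, resid_sd),
                        0.08,
                        0.55,
                    )
                )
                ssi = float(master.normal(gcfg.ssi_mean, gcfg.ssi_sd))
                seed = int(master.integers(0, 2**31 - 1))
                spec = AngiogramSpec(
                    field_mm=sim.field_mm,
                    image_px=sim.image_px,
                    capillary_fraction_target=frac,
                    n_large_vessels=sim.n_large_vessels,
                    noise_sd=sim.noise_sd,
                    ssi=ssi,
                    laterality=eye,
                    seed=seed,
                    separability_cutoff_um=config.segmentation.caliber_cutoff_um,
                )
                angiogram, gt = generate_angiogram(spec)
                eye_id = f"{subject_id}_{eye}"
                write_angiogram(
                    angiogram,
                    out / "images" / f"{eye_id}.png",
                    extra_metadata={
                        "subject_id": subject_id,
                        "group": gcfg.name,
                        "seed": seed,
                        "capillary_fraction_target": frac,
                        "true_capillary_density_whole": gt.true_capillary_density_whole,
                        "true_capillary_density_annulus": gt.true_capillary_density_annulus,
                    },
                )
                write_mask(gt.capillary_mask, out / "masks" / f"{eye_id}_gt_capillary.png")
                write_mask(gt.large_vessel_mask, out / "masks" / f"{eye_id}_gt_large.png")

                if config.quality.enforce_ssi_gate and ssi <= config.quality.min_ssi:
                    exclusions[gcfg.name] = exclusions.get(gcfg.name, 0) + 1
                    log_lines.append(
                        f"excluded {eye_id}: ssi {ssi:.1f} <= gate {config.quality.min_ssi}"
                    )
                    continue

                n = sim.image_px
                rings = build_rings(
                    ((n - 1) / 2.0, (n - 1) / 2.0),
                    config.geometry.inner_diameter_mm,
                    config.geometry.outer_diameter_mm,
                    angiogram.scale_um_per_px,
                    angiogram.shape,
                    laterality=eye,
                    nasal_right_for_od=config.geometry.nasal_right_for_od,
                )
                commercial, custom = measure_eye(
                    angiogram,
                    rings=rings,
                    caliber_cutoff_um=config.segmentation.caliber_cutoff_um,
                    convention=config.density.convention,
                    threshold_method=config.segmentation.method,
                    rim_dilation_px=config.segmentation.rim_dilation_px,
                    enforce_quality=config.quality.enforce_ssi_gate,
                )
                log_lines.append(
                    f"measured {eye_id}: threshold={custom.provenance['threshold_value']:.4f} "
                    f"pcd={custom.whole_pcd:.1f}% commercial={commercial.whole_pcd:.1f}%"
                )
                (out / "reports" / f"{eye_id}.json").write_text(
                    json.dumps(
                        {"commercial_style": commercial.to_dict(), "custom_capillary": custom.to_dict()},
                        indent=2,
                        sort_keys=True,
                    )
                )
                rows.extend(_rows_for_eye(subject_id, eye, gcfg.name, ssi, commercial, custom))
                paired.append((eye_id, custom.whole_pcd, commercial.whole_pcd, ssi))

    table = pd.DataFrame(rows, columns=["subject_id", "eye", "group", "metric", "value", "ssi"])
    table.to_csv(out / "tables" / "cohort.csv", index=False)

    stats_summary: Dict = {"exclusions": exclusions}

    contrast_rows = []
    for metric in ("pcd_whole", "pcd_nasal", "commercial_whole"):
        try:
            res = compare_groups(table, metric)
        except ValidationError as exc:
            log_lines.append(f"compare_groups skipped for {metric}: {exc}")
            continue
        for c in res.contrasts:
            contrast_rows.append(
                {
                    "metric": metric,
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "estimate": c.estimate,
                    "se": c.se,
                    "z": c.z,
                    "p_raw": c.p_raw,
                    "p_adjusted": c.p_adjusted,
                    "p_display": c.p_display,
                    "method": c.method,
                }
            )
    pd.DataFrame(contrast_rows).to_csv(out / "stats" / "contrasts.csv", index=False)

    if len(paired) >= 3:
        custom_vals = [p[1] for p in paired]
        commercial_vals = [p[2] for p in paired]
        ba = bland_altman(custom_vals, commercial_vals)
        stats_summary["bland_altman"] = ba.to_dict()
        diffs = [c - u for _, u, c, _ in paired]
        ssis = [s for _, _, _, s in paired]
        try:
            r, p = quality_disagreement_correlation(diffs, ssis)
            stats_summary["ssi_disagreement"] = {"r": r, "p": p}
        except UndefinedStatisticError as exc:
            log_lines.append(f"ssi correlation undefined: {exc}")

    try:
        roc = roc_analysis(
            table,
            config.stats.roc_metric,
            config.stats.roc_positive_group,
            config.stats.roc_negative_group,
            direction="higher",
        )
        stats_summary["roc"] = roc.to_dict()
    except ValidationError as exc:
        log_lines.append(f"roc skipped: {exc}")

    (out / "stats" / "summary.json").write_text(
        json.dumps(stats_summary, indent=2, sort_keys=True)
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")

    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": config.to_dict(),
        "n_eyes_measured": len(paired),
        "exclusions": exclusions,
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
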