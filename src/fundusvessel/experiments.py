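"""Built-in validation experiments on the synthetic fundus simulator.

These are the package's standing accuracy checks: each function builds
seeded synthetic inputs with known ground truth, runs the full measurement
pipeline on them, and reports how well the truth is recovered.  They back
the test suite and the reproduction script, and are cheap enough to run
interactively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .av_labeling import label_vessels
from .group_stats import genotype_report, percent_increase, percent_of_reference, summarize_image
from .radial_scan import DiscGeometry, ScanConfig, analyze_image
from .synthetic import SimSpec, VesselSpec, generate, generate_cohort

#: Example per-genotype mean retinal vessel diameters (px) from a mouse
#: Mitf-variant genotype comparison; used as ready-made inputs for the
#: percent-ratio helpers in examples and validation runs.  Keys: vessel
#: class -> (wild-type mean, {variant genotype: variant mean}).
REFERENCE_GROUP_MEANS = {
    "artery": (13.3684, {"enu22": 14.0229, "vga9": 14.0109}),
    "vein": (13.4198, {"enu22": 15.9425, "vga9": 14.8438}),
    "both": (13.3941, {"enu22": 14.9683, "vga9": 14.4273}),
}


def reference_ratio_table() -> pd.DataFrame:
    """Percent-of-reference and percent-increase for the bundled example
    genotype means (wild type as reference)."""
    rows = []
    for label, (ref, variants) in REFERENCE_GROUP_MEANS.items():
        for genotype, mean in variants.items():
            rows.append({
                "label": label, "genotype": genotype,
                "group_mean": mean, "reference_mean": ref,
                "percent_of_reference": percent_of_reference(mean, ref),
                "percent_increase": percent_increase(mean, ref),
            })
    return pd.DataFrame(rows)


def _default_disc() -> tuple[SimSpec, DiscGeometry]:
    spec = SimSpec()
    return spec, DiscGeometry(center=spec.disc_center,
                              disc_radius=spec.disc_radius)


# ---------------------------------------------------------------------------
# Width recovery
# ---------------------------------------------------------------------------

def width_recovery_experiment(
        widths: tuple[float, ...] = (4, 6, 8, 10, 12, 14, 16, 18, 20),
        obliquities_deg: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0),
        seed: int = 0) -> pd.DataFrame:
    """Measure single synthetic ribbons over a width x obliquity grid.

    Each cell renders one noiseless vessel at a seed-jittered generic
    angle (kept off the pixel axes, where exact-tie rasterisation makes
    the half-intensity contour ambiguous), runs the pipeline, and records
    truth vs measured width and the tolerance max(1.5 px, 5% of truth).
    """
    base, disc = _default_disc()
    rng = np.random.default_rng(seed)
    rows = []
    for w in widths:
        for ob in obliquities_deg:
            angle = float(rng.uniform(0.1, 0.4) + rng.integers(0, 4)
                          * math.pi / 2)
            spec = SimSpec(vessels=(VesselSpec(angle=angle, width=float(w),
                                               obliquity_deg=float(ob)),),
                           noise_sd=0.0, seed=seed)
            image, mask, _ = generate(spec)
            measurements = analyze_image(image, mask, disc)
            measured = measurements[0].mean if measurements else float("nan")
            tol = max(1.5, 0.05 * w)
            rows.append({"width": w, "obliquity_deg": ob, "angle": angle,
                         "measured": measured, "error": measured - w,
                         "tolerance": tol,
                         "within_tolerance": abs(measured - w) <= tol})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Vessel count recovery
# ---------------------------------------------------------------------------

def count_recovery_experiment(n_runs: int = 100, seed: int = 0,
                              noise_sd: float = 5.0) -> pd.DataFrame:
    """Recover the vessel count on seeded clean layouts of 4-8 vessels.

    Layout parameters (moderate angular jitter and obliquity) keep the
    ribbons non-overlapping in the annulus so the simulated count is the
    unambiguous truth.
    """
    from .synthetic import random_layout

    base, disc = _default_disc()
    children = np.random.SeedSequence(seed).spawn(n_runs)
    rows = []
    for i, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(child_seed)
        n_vessels = int(rng.integers(4, 9))
        vessels = random_layout(rng, n_vessels, artery_width_mean=9.0,
                                vein_width_mean=13.0, width_sd=1.0,
                                max_obliquity_deg=20.0, angle_jitter=0.15)
        spec = SimSpec(vessels=vessels, noise_sd=noise_sd, seed=child_seed)
        image, mask, _ = generate(spec)
        found = len(analyze_image(image, mask, disc))
        rows.append({"run": i, "seed": child_seed, "true_count": n_vessels,
                     "found_count": found, "correct": found == n_vessels})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Effect-size recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSizeResult:
    n_images_per_group: int
    vein_percent_increase: float
    true_percent_increase: float
    report: pd.DataFrame


def effect_size_experiment(n_images: int = 6, seed: int = 0,
                           vein_mean_ref: float = 12.0,
                           vein_mean_alt: float = 14.0,
                           artery_mean: float = 10.0,
                           width_sd: float = 1.0,
                           noise_sd: float = 3.0) -> EffectSizeResult:
    """Estimate a known between-group venular width effect end to end.

    Two cohorts are simulated whose vein widths are drawn around
    ``vein_mean_ref`` (reference) and ``vein_mean_alt``; every image is
    measured, labeled and summarised, and the genotype report's venular
    percent_increase is compared with the generative truth
    ``100 * (alt - ref) / ref``.
    """
    base, disc = _default_disc()
    seeds = np.random.SeedSequence(seed).spawn(2)
    cohorts = {
        "reference": generate_cohort(
            n_images, "reference", artery_width_mean=artery_mean,
            vein_width_mean=vein_mean_ref, width_sd=width_sd,
            noise_sd=noise_sd,
            seed=int(seeds[0].generate_state(1)[0] % (2**31 - 1))),
        "variant": generate_cohort(
            n_images, "variant", artery_width_mean=artery_mean,
            vein_width_mean=vein_mean_alt, width_sd=width_sd,
            noise_sd=noise_sd,
            seed=int(seeds[1].generate_state(1)[0] % (2**31 - 1))),
    }
    image_results = []
    for cohort in cohorts.values():
        for item in cohort:
            measurements = label_vessels(
                analyze_image(item.image, item.mask, disc, ScanConfig()))
            image_results.append(
                summarize_image(measurements, item.image_id, item.group_label))
    report = genotype_report(image_results, reference_group="reference")
    row = report[(report.metric == "mean_diameter")
                 & (report.label == "vein")].iloc[0]
    truth = 100.0 * (vein_mean_alt - vein_mean_ref) / vein_mean_ref
    return EffectSizeResult(n_images_per_group=n_images,
                            vein_percent_increase=float(row.percent_increase),
                            true_percent_increase=truth,
                            report=report)
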