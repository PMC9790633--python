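"""Seeded synthetic fundus angiograms with known vessel geometry.

The generator emulates the features of a mouse fluorescein angiogram that
the ring-scan algorithm actually relies on: a bright circular optic disc, a
darker fundus background (with an "elevated" variant mimicking the raised
background of hypopigmented eyes), vessels radiating outward from the disc
edge as bright ribbons of specified perpendicular width crossing the
2x-4x disc-radius measurement annulus, and additive Gaussian sensor noise
clipped to the intensity range.  It does not attempt photorealism: no
capillary plexus, no dye leakage beyond a uniform background raise, no
vignetting.

Every image comes with a ground-truth record (per-vessel centreline
parameters, width, artery/vein label from alternating construction) and the
binary ribbon-union mask, so each pipeline stage can be tested against
truth without any external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .image_io import FundusImage, VesselMask


@dataclass(frozen=True)
class VesselSpec:
    """One straight (optionally bent) ribbon vessel.

    angle
        Position around the disc, radians clockwise from 12 o'clock.
    width
        Perpendicular ribbon width, px.
    intensity
        Plateau intensity of the ribbon (before noise).
    obliquity_deg
        Angle between the vessel course and the radial direction at the
        disc edge; 0 = perfectly radial.
    curvature
        Optional quadratic bend: lateral offset (px) at unit arc length^2,
        i.e. offset = curvature * (s / 100)^2 px after s px of arc.
    """

    angle: float
    width: float
    intensity: float = 230.0
    obliquity_deg: float = 0.0
    curvature: float = 0.0


@dataclass(frozen=True)
class SimSpec:
    """Full description of one synthetic fundus image."""

    shape: tuple[int, int] = (320, 320)
    disc_center: tuple[float, float] = (160.0, 160.0)
    disc_radius: float = 36.0
    disc_intensity: float = 245.0
    background: float = 40.0        # elevated (~90+) emulates hypopigmentation
    vessels: tuple[VesselSpec, ...] = ()
    noise_sd: float = 0.0
    bit_depth: int = 8
    seed: int = 0
    clean: bool = True              # reject vessel overlap within the annulus

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.disc_radius <= 0:
            raise ConfigError("disc_radius must be > 0")
        max_value = (1 << self.bit_depth) - 1
        if not (0 <= self.background <= max_value):
            raise ConfigError("background outside intensity range")


@dataclass(frozen=True)
class TruthVessel:
    vessel_id: int
    angle: float
    width: float
    obliquity_deg: float
    curvature: float
    label: str                  # artery | vein by alternating construction
    origin: tuple[float, float]     # centreline start (row, col), disc edge
    direction: tuple[float, float]  # unit (row, col) course at the origin


@dataclass(frozen=True)
class GroundTruth:
    vessels: tuple[TruthVessel, ...]
    mask: np.ndarray            # bool, ribbon union at the half-intensity contour


def _unit(angle: float) -> tuple[float, float]:
    """Unit (row, col) vector at ``angle`` clockwise from 12 o'clock, y down."""
    return (-math.cos(angle), math.sin(angle))


def _vessel_frame(spec: SimSpec, v: VesselSpec) -> tuple[np.ndarray, np.ndarray]:
    """Centreline origin (on the disc edge) and unit course direction."""
    radial = np.array(_unit(v.angle))
    origin = np.array(spec.disc_center) + spec.disc_radius * radial
    psi = math.radians(v.obliquity_deg)
    # rotate the radial direction by the obliquity (in display coords, a
    # positive obliquity turns the course clockwise on screen)
    rot = np.array([[math.cos(psi), -math.sin(psi)],
                    [math.sin(psi), math.cos(psi)]])
    direction = rot @ radial
    return origin, direction


def _ribbon_field(spec: SimSpec, v: VesselSpec,
                  rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    """Per-pixel coverage in [0, 1] of one ribbon (1 px soft edge).

    The ribbon is the set of points within ``width/2`` of a ray starting at
    the disc edge; coverage ramps linearly over 1 px across the boundary,
    approximating area coverage of an anti-aliased edge.
    """
    origin, direction = _vessel_frame(spec, v)
    dr = rr - origin[0]
    dc = cc - origin[1]
    s = dr * direction[0] + dc * direction[1]          # along-course arc length
    lateral = dr * (-direction[1]) + dc * direction[0]  # signed perpendicular
    if v.curvature:
        lateral = lateral - v.curvature * (np.maximum(s, 0.0) / 100.0) ** 2
    dist = np.abs(lateral)
    # behind the origin the distance is to the ray's start point
    behind = s < 0
    if behind.any():
        dist = np.where(behind, np.hypot(dr, dc), dist)
    coverage = np.clip(0.5 + (v.width / 2.0 - dist), 0.0, 1.0)
    return coverage


def _check_clean(spec: SimSpec, coverages: Sequence[np.ndarray],
                 rr: np.ndarray, cc: np.ndarray) -> None:
    """Reject ribbon overlap inside the measurement annulus for clean specs."""
    r = np.hypot(rr - spec.disc_center[0], cc - spec.disc_center[1])
    annulus = (r >= 2 * spec.disc_radius - 2) & (r <= 4 * spec.disc_radius + 2)
    solid = np.zeros(rr.shape, dtype=np.int16)
    for cov in coverages:
        solid += (cov > 0.5).astype(np.int16)
    if np.any((solid > 1) & annulus):
        raise ConfigError(
            "vessel ribbons overlap within the measurement annulus under a "
            "'clean' spec; widen the angular separation or set clean=False")


def generate(spec: SimSpec) -> tuple[FundusImage, VesselMask, GroundTruth]:
    """Render a synthetic fundus image, its vessel mask, and ground truth.

    Deterministic for a fixed spec (including seed).  Vessels with even
    index are labeled "artery", odd "vein", mirroring the alternating
    layout the labeling stage assumes; construct specs accordingly when the
    alternation matters.
    """
    nrows, ncols = spec.shape
    max_value = (1 << spec.bit_depth) - 1
    rr, cc = np.meshgrid(np.arange(nrows, dtype=np.float64),
                         np.arange(ncols, dtype=np.float64), indexing="ij")

    img = np.full(spec.shape, float(spec.background))

    # optic disc: soft-edged bright circle
    rdist = np.hypot(rr - spec.disc_center[0], cc - spec.disc_center[1])
    disc_cov = np.clip(0.5 + (spec.disc_radius - rdist), 0.0, 1.0)
    img = img + disc_cov * (spec.disc_intensity - img)

    coverages = [_ribbon_field(spec, v, rr, cc) for v in spec.vessels]
    if spec.clean and len(coverages) > 1:
        _check_clean(spec, coverages, rr, cc)
    for v, cov in zip(spec.vessels, coverages):
        img = img + cov * np.maximum(v.intensity - img, 0.0)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    img = np.clip(np.round(img), 0, max_value)

    mask = np.zeros(spec.shape, dtype=bool)
    for cov in coverages:
        mask |= cov > 0.5

    truth_vessels = []
    for i, v in enumerate(spec.vessels):
        origin, direction = _vessel_frame(spec, v)
        truth_vessels.append(TruthVessel(
            vessel_id=i, angle=v.angle, width=v.width,
            obliquity_deg=v.obliquity_deg, curvature=v.curvature,
            label="artery" if i % 2 == 0 else "vein",
            origin=(float(origin[0]), float(origin[1])),
            direction=(float(direction[0]), float(direction[1]))))

    image = FundusImage(img, bit_depth=spec.bit_depth, source_path=None)
    return image, VesselMask(mask), GroundTruth(vessels=tuple(truth_vessels),
                                                mask=mask)


# ---------------------------------------------------------------------------
# Layout helpers
# ---------------------------------------------------------------------------

def alternating_layout(n_vessels: int,
                       artery_width: float, vein_width: float,
                       intensity: float = 230.0,
                       obliquity_deg: float = 0.0,
                       phase: float = 0.0) -> tuple[VesselSpec, ...]:
    """Evenly spaced vessels alternating artery/vein widths around the disc."""
    if n_vessels < 1:
        raise ConfigError("need at least one vessel")
    step = 2 * math.pi / n_vessels
    return tuple(
        VesselSpec(angle=(phase + i * step) % (2 * math.pi),
                   width=artery_width if i % 2 == 0 else vein_width,
                   intensity=intensity, obliquity_deg=obliquity_deg)
        for i in range(n_vessels))


def random_layout(rng: np.random.Generator, n_vessels: int,
                  artery_width_mean: float, vein_width_mean: float,
                  width_sd: float = 1.0, intensity: float = 230.0,
                  max_obliquity_deg: float = 25.0,
                  angle_jitter: float = 0.25) -> tuple[VesselSpec, ...]:
    """Alternating layout with jittered angles, random widths/obliquities.

    Angles stay separated by at least ~half the even spacing so clean specs
    remain clean; widths are normal draws clipped at 2 px.
    """
    step = 2 * math.pi / n_vessels
    phase = rng.uniform(0, 2 * math.pi)
    vessels = []
    for i in range(n_vessels):
        mean_w = artery_width_mean if i % 2 == 0 else vein_width_mean
        width = float(max(2.0, rng.normal(mean_w, width_sd)))
        jitter = rng.uniform(-angle_jitter, angle_jitter) * step
        vessels.append(VesselSpec(
            angle=(phase + i * step + jitter) % (2 * math.pi),
            width=width, intensity=intensity,
            obliquity_deg=float(rng.uniform(-max_obliquity_deg,
                                            max_obliquity_deg))))
    return tuple(vessels)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortImage:
    image_id: str
    group_label: str
    seed: int
    image: FundusImage
    mask: VesselMask
    truth: GroundTruth


def generate_cohort(n_images: int,
                    group_label: str,
                    artery_width_mean: float = 10.0,
                    vein_width_mean: float = 13.0,
                    width_sd: float = 1.0,
                    n_vessels: int = 6,
                    background: float = 40.0,
                    noise_sd: float = 3.0,
                    seed: int = 0,
                    base: SimSpec = SimSpec()) -> list[CohortImage]:
    """Generate a seeded cohort of images with per-label width draws.

    Per-image vessel widths are drawn from Normal(mean, sd) per label
    (clipped at 2 px); the per-image child seeds derive deterministically
    from ``seed`` via a SeedSequence spawn, and are recorded in the output.
    """
    if n_images < 1:
        raise ConfigError("n_images must be >= 1")
    if width_sd < 0:
        raise ConfigError("width_sd must be >= 0")
    children = np.random.SeedSequence(seed).spawn(n_images)
    cohort = []
    for i, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(child_seed)
        # rejection-sample layouts until the ribbons are disjoint in the
        # annulus (oblique neighbours can converge); deterministic because
        # the redraws continue the same child stream
        for _attempt in range(50):
            vessels = random_layout(rng, n_vessels,
                                    artery_width_mean, vein_width_mean,
                                    width_sd=width_sd)
            spec = SimSpec(shape=base.shape, disc_center=base.disc_center,
                           disc_radius=base.disc_radius,
                           disc_intensity=base.disc_intensity,
                           background=background, vessels=vessels,
                           noise_sd=noise_sd, bit_depth=base.bit_depth,
                           seed=child_seed)
            try:
                image, mask, truth = generate(spec)
                break
            except ConfigError:
                continue
        else:
            raise ConfigError(
                f"could not draw a non-overlapping {n_vessels}-vessel layout "
                f"in 50 attempts (image {i})")
        cohort.append(CohortImage(image_id=f"{group_label}_{i:03d}",
                                  group_label=group_label, seed=child_seed,
                                  image=image, mask=mask, truth=truth))
    return cohort


# ---------------------------------------------------------------------------
# On-disk export (used by the CLI `simulate` command)
# ---------------------------------------------------------------------------

def write_simulation(spec: SimSpec, out_dir: str | Path,
                     stem: str = "synthetic") -> dict[str, Path]:
    """Write image PNG, mask PNG, truth CSV and reproducibility metadata."""
    from .image_io import save_image, save_mask  # local to avoid cycle at import

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image, mask, truth = generate(spec)
    paths = {
        "image": out / f"{stem}_image.png",
        "mask": out / f"{stem}_mask.png",
        "truth": out / f"{stem}_truth.csv",
        "meta": out / f"{stem}_meta.json",
    }
    save_image(image, paths["image"])
    save_mask(mask, paths["mask"])
    import pandas as pd

    pd.DataFrame([asdict(v) for v in truth.vessels]).to_csv(
        paths["truth"], index=False)
    meta = asdict(spec)
    meta["vessels"] = [asdict(v) for v in spec.vessels]
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return paths
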