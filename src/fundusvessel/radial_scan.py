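"""Concentric-ring intensity scanning and vessel diameter measurement.

The measurement model
---------------------

Mouse retinal vessels radiate from the optic disc, so a circle centred on
the disc crosses every major vessel roughly perpendicular to its course.
The algorithm samples image intensity along ``n_rings`` concentric circles
spanning the annulus from ``inner_factor`` (default 2) to ``outer_factor``
(default 4) times the disc radius — far enough out to escape the disc's own
brightness, close enough in that the primary vessels have not yet branched.

On each ring the intensity profile is scanned clockwise; a rising crossing
of the detection threshold marks a vessel *start* (entering a bright
vessel), a falling crossing marks an *end*.  Start/end pairs are chained
across rings into per-vessel tracks by angular proximity, and each start
point's diameter is the shortest Euclidean distance to any end point of the
same vessel across all of its rings — which for a ribbon-like vessel is its
perpendicular width regardless of how obliquely it crosses the ring.

Coordinate conventions: image arrays are indexed (row, col) with the origin
top-left; ring angles are measured clockwise from 12 o'clock in display
coordinates (y increasing downward), reported in [0, 2*pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    ConfigError,
    GeometryError,
    MeasurementError,
    NoBackgroundError,
)
from .image_io import FundusImage, VesselMask, enhance_with_mask


# ---------------------------------------------------------------------------
# Geometry and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscGeometry:
    """Optic-disc centre (subpixel row, col) and radius in pixels."""

    center: tuple[float, float]
    disc_radius: float

    def __post_init__(self) -> None:
        if self.disc_radius <= 0:
            raise GeometryError(f"disc radius must be > 0, got {self.disc_radius}")

    def validate_bounds(self, shape: tuple[int, int], outer_factor: float) -> None:
        """Require the outermost ring to lie fully inside the image."""
        r = outer_factor * self.disc_radius
        row, col = self.center
        if (row - r < 0 or col - r < 0
                or row + r > shape[0] - 1 or col + r > shape[1] - 1):
            raise GeometryError(
                f"outer ring (radius {r:.1f} px at centre {self.center}) "
                f"exceeds image bounds {shape}"
            )


@dataclass(frozen=True)
class ScanConfig:
    """Tunable parameters of the ring scan.

    threshold_fraction
        Detection threshold as a fraction of the intensity scale, default
        0.80.  With ``threshold_relative_to="bit_depth"`` the scale is the
        maximum representable value (204 for 8-bit); ``"image_max"`` uses
        the observed image maximum instead.
    n_rings
        Number of concentric sampling circles, default 30.
    inner_factor / outer_factor
        Annulus bounds as multiples of the disc radius, defaults 2 and 4.
    max_angle_gap
        Angular tolerance (radians) when chaining crossings ring-to-ring.
        ``None`` (default) resolves to ``2*atan(15 / inner_radius)`` at
        analysis time — about the angular footprint of a 30 px-wide vessel
        on the innermost ring.
    min_ring_support
        Fraction of rings a chain must appear on to count as a vessel.
    drop_first_ring
        Exclude the innermost ring from the diameter series, yielding 29
        values per vessel under the defaults.
    """

    threshold_fraction: float = 0.80
    n_rings: int = 30
    inner_factor: float = 2.0
    outer_factor: float = 4.0
    max_angle_gap: float | None = None
    min_ring_support: float = 0.8
    threshold_relative_to: str = "bit_depth"  # or "image_max"
    drop_first_ring: bool = False
    #: optional per-vessel inner-radius overrides (vessel_id -> radius px),
    #: for starting a vessel's series just past a branch point.
    inner_radius_overrides: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.threshold_fraction <= 1):
            raise ConfigError(
                f"threshold_fraction must be in (0, 1], got {self.threshold_fraction}")
        if self.n_rings < 2:
            raise ConfigError(f"n_rings must be >= 2, got {self.n_rings}")
        if self.inner_factor >= self.outer_factor:
            raise ConfigError(
                f"inner_factor ({self.inner_factor}) must be < outer_factor "
                f"({self.outer_factor})")
        if not (0 < self.min_ring_support <= 1):
            raise ConfigError(
                f"min_ring_support must be in (0, 1], got {self.min_ring_support}")
        if self.threshold_relative_to not in ("bit_depth", "image_max"):
            raise ConfigError(
                f"threshold_relative_to must be 'bit_depth' or 'image_max', "
                f"got {self.threshold_relative_to!r}")

    def resolve_threshold(self, image: FundusImage) -> float:
        scale = (image.max_value if self.threshold_relative_to == "bit_depth"
                 else float(image.pixels.max()))
        return self.threshold_fraction * scale

    def resolve_angle_gap(self, inner_radius: float) -> float:
        if self.max_angle_gap is not None:
            return self.max_angle_gap
        return 2.0 * math.atan(15.0 / inner_radius)


# ---------------------------------------------------------------------------
# Ring sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingProfile:
    """Intensity samples along one circle, clockwise from 12 o'clock."""

    ring_index: int
    radius: float
    center: tuple[float, float]
    angles: np.ndarray      # strictly increasing in [0, 2*pi)
    intensities: np.ndarray

    def point_at(self, angle: float) -> tuple[float, float]:
        """Subpixel (row, col) of the ring point at ``angle``."""
        row = self.center[0] - self.radius * math.cos(angle)
        col = self.center[1] + self.radius * math.sin(angle)
        return (row, col)


class Polarity(str, Enum):
    START = "start"
    END = "end"


@dataclass(frozen=True)
class Crossing:
    """A threshold crossing on one ring: a vessel edge point."""

    ring_index: int
    angle: float
    point: tuple[float, float]
    polarity: Polarity


def ring_radii(disc: DiscGeometry, config: ScanConfig,
               image_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Evenly spaced ring radii spanning the measurement annulus.

    ``n_rings`` radii from ``inner_factor*disc_radius`` to
    ``outer_factor*disc_radius`` inclusive.  If ``image_shape`` is given the
    outermost ring is checked against the bounds.
    """
    if image_shape is not None:
        disc.validate_bounds(image_shape, config.outer_factor)
    return np.linspace(config.inner_factor * disc.disc_radius,
                       config.outer_factor * disc.disc_radius,
                       config.n_rings)


def sample_ring(image: FundusImage, center: tuple[float, float],
                radius: float, ring_index: int = 0) -> RingProfile:
    """Bilinearly sample the image on a circle at ~1 px arc spacing.

    The sample count is ``ceil(2*pi*radius)`` so neighbouring samples are
    about one pixel apart along the arc, matching pixel-level edge
    localisation.
    """
    if radius <= 0:
        raise GeometryError(f"ring radius must be > 0, got {radius}")
    row0, col0 = center
    nrows, ncols = image.shape
    if (row0 - radius < 0 or col0 - radius < 0
            or row0 + radius > nrows - 1 or col0 + radius > ncols - 1):
        raise GeometryError(
            f"ring of radius {radius:.1f} at centre ({row0:.1f}, {col0:.1f}) "
            f"exceeds image bounds {image.shape}")
    n = max(8, math.ceil(2 * math.pi * radius))
    angles = np.arange(n) * (2 * math.pi / n)
    rows = row0 - radius * np.cos(angles)
    cols = col0 + radius * np.sin(angles)
    vals = ndimage.map_coordinates(image.pixels, np.vstack([rows, cols]),
                                   order=1, mode="nearest")
    return RingProfile(ring_index=ring_index, radius=float(radius),
                       center=(float(row0), float(col0)),
                       angles=angles, intensities=vals)


# ---------------------------------------------------------------------------
# Crossing detection
# ---------------------------------------------------------------------------

def detect_crossings(profile: RingProfile, threshold: float) -> list[Crossing]:
    """Find vessel start/end points where the profile crosses ``threshold``.

    The scan origin is rotated to the first below-threshold sample so that
    no vessel straddles the angular seam; a *start* is emitted at each
    below -> (>= threshold) transition and an *end* at each
    (>= threshold) -> below transition.  Crossing angles are refined by
    linear interpolation between the two bracketing samples.  Starts and
    ends therefore strictly alternate with equal counts.

    Raises :class:`NoBackgroundError` if every sample is at or above the
    threshold (the ring contains no background and vessels cannot be
    delimited).
    """
    vals = np.asarray(profile.intensities, dtype=np.float64)
    if vals.size == 0:
        raise MeasurementError("empty ring profile")
    above = vals >= threshold
    if above.all():
        raise NoBackgroundError(
            f"ring {profile.ring_index} (radius {profile.radius:.1f}): every "
            f"sample >= threshold {threshold:.1f}; no background on ring")
    if not above.any():
        return []
    n = vals.size
    origin = int(np.argmin(above))          # first below-threshold sample
    rolled = np.roll(above, -origin)
    # transitions in the rolled frame; rolled[0] is False by construction and
    # the cycle is closed by re-appending it, so a pulse reaching the end of
    # the rolled frame still gets its end crossing
    diffs = np.diff(np.append(rolled, rolled[0]).astype(np.int8))
    two_pi = 2 * math.pi
    step = two_pi / n

    crossings: list[Crossing] = []
    for idx in np.flatnonzero(diffs):
        polarity = Polarity.START if diffs[idx] == 1 else Polarity.END
        i0 = (origin + idx) % n             # last sample on the old side
        i1 = (i0 + 1) % n
        v0, v1 = vals[i0], vals[i1]
        frac = 0.5 if v1 == v0 else float(np.clip((threshold - v0) / (v1 - v0), 0, 1))
        angle = (profile.angles[i0] + frac * step) % two_pi
        crossings.append(Crossing(ring_index=profile.ring_index,
                                  angle=float(angle),
                                  point=profile.point_at(float(angle)),
                                  polarity=polarity))
    starts = sum(c.polarity is Polarity.START for c in crossings)
    assert starts * 2 == len(crossings), "starts and ends must balance"
    return crossings


def _pulses(crossings: Sequence[Crossing]) -> list[tuple[Crossing, Crossing]]:
    """Pair alternating start/end crossings of one ring into pulses."""
    ordered = sorted(crossings, key=lambda c: c.angle)
    # rotate so the list begins with a start (detection guarantees alternation)
    k = next((i for i, c in enumerate(ordered) if c.polarity is Polarity.START), 0)
    ordered = ordered[k:] + ordered[:k]
    return [(ordered[i], ordered[i + 1]) for i in range(0, len(ordered) - 1, 2)]


# ---------------------------------------------------------------------------
# Chaining crossings into vessels
# ---------------------------------------------------------------------------

@dataclass
class VesselChain:
    """Start/end pulse pairs of one vessel across the rings it spans."""

    vessel_id: int
    crossings: dict[int, tuple[Crossing, Crossing]]  # ring_index -> (start, end)
    anchor_angle: float = 0.0

    @property
    def n_rings(self) -> int:
        return len(self.crossings)

    def start_points(self) -> list[tuple[int, tuple[float, float]]]:
        return [(r, p[0].point) for r, p in sorted(self.crossings.items())]

    def end_points(self) -> list[tuple[float, float]]:
        return [p[1].point for _, p in sorted(self.crossings.items())]


def _angdist(a: float, b: float) -> float:
    d = abs(a - b) % (2 * math.pi)
    return min(d, 2 * math.pi - d)


def chain_vessels(per_ring_crossings: Sequence[Sequence[Crossing]],
                  config: ScanConfig,
                  inner_radius: float | None = None) -> list[VesselChain]:
    """Link start/end pulses across rings into per-vessel chains.

    Greedy nearest-angle matching: each ring's pulses are matched to the
    open chain whose most recent start angle is closest, provided the
    angular distance is within ``max_angle_gap``; unmatched pulses open new
    chains.  Matching against the *latest* angle (rather than a global
    mean) lets chains track the steady angular drift of obliquely crossing
    vessels.  Chains spanning fewer than ``min_ring_support * n_rings``
    rings are dropped; survivors are renumbered in order of mean start
    angle.
    """
    n_rings = len(per_ring_crossings)
    if n_rings == 0:
        return []
    if inner_radius is None:
        inner_radius = 100.0
    gap = config.resolve_angle_gap(inner_radius)

    chains: list[dict] = []   # {rings: {ring: pulse}, last_angle, angles}
    for ring_idx, crossings in enumerate(per_ring_crossings):
        pulses = _pulses(crossings)
        # candidate (distance, pulse_slot, chain_slot) pairs, greedily matched
        cands = []
        for pi, (start, _end) in enumerate(pulses):
            for ci, ch in enumerate(chains):
                d = _angdist(start.angle, ch["last_angle"])
                if d <= gap:
                    cands.append((d, pi, ci))
        cands.sort(key=lambda t: t[0])
        used_p: set[int] = set()
        used_c: set[int] = set()
        for d, pi, ci in cands:
            if pi in used_p or ci in used_c:
                continue
            if ring_idx in chains[ci]["rings"]:
                continue
            used_p.add(pi)
            used_c.add(ci)
            chains[ci]["rings"][ring_idx] = pulses[pi]
            chains[ci]["last_angle"] = pulses[pi][0].angle
            chains[ci]["angles"].append(pulses[pi][0].angle)
        for pi, pulse in enumerate(pulses):
            if pi not in used_p:
                chains.append({"rings": {ring_idx: pulse},
                               "last_angle": pulse[0].angle,
                               "angles": [pulse[0].angle]})

    min_support = config.min_ring_support * n_rings
    kept = [ch for ch in chains if len(ch["rings"]) >= min_support]

    def mean_angle(angles: list[float]) -> float:
        s = sum(math.sin(a) for a in angles)
        c = sum(math.cos(a) for a in angles)
        return math.atan2(s, c) % (2 * math.pi)

    result = [VesselChain(vessel_id=0, crossings=dict(ch["rings"]),
                          anchor_angle=mean_angle(ch["angles"]))
              for ch in kept]
    result.sort(key=lambda v: v.anchor_angle)
    for i, v in enumerate(result):
        v.vessel_id = i
    return result


# ---------------------------------------------------------------------------
# Diameter measurement
# ---------------------------------------------------------------------------

@dataclass
class VesselMeasurement:
    """Per-vessel diameter series with its summary statistics."""

    vessel_id: int
    anchor_angle: float
    ring_indices: list[int]
    diameters: np.ndarray   # px, one per ring the chain spans
    mean: float
    median: float
    sd: float
    label: str = "unknown"  # artery | vein | unknown

    @property
    def n_rings(self) -> int:
        return len(self.diameters)


def measure_vessel(chain: VesselChain) -> VesselMeasurement:
    """Diameter series of one vessel by shortest start-to-end distances.

    For each ring's start point the diameter is the minimum Euclidean
    distance from that start point to *any* end point of the same chain,
    across all the rings it spans.  For a straight ribbon this minimum is
    the ribbon's perpendicular width, independent of how obliquely the
    vessel crosses the rings.  Ties take the end point of the lowest ring
    index (the distance is unaffected).
    """
    if chain.n_rings == 0:
        raise MeasurementError(f"vessel {chain.vessel_id}: empty chain")
    ends = np.array(chain.end_points(), dtype=np.float64)
    if ends.size == 0:
        raise MeasurementError(f"vessel {chain.vessel_id}: no end points")
    ring_indices = []
    diameters = []
    for ring_idx, start in chain.start_points():
        d = np.hypot(ends[:, 0] - start[0], ends[:, 1] - start[1]).min()
        ring_indices.append(ring_idx)
        diameters.append(float(d))
    diam = np.asarray(diameters)
    sd = float(diam.std(ddof=1)) if diam.size > 1 else 0.0
    return VesselMeasurement(vessel_id=chain.vessel_id,
                             anchor_angle=chain.anchor_angle,
                             ring_indices=ring_indices,
                             diameters=diam,
                             mean=float(diam.mean()),
                             median=float(np.median(diam)),
                             sd=sd)


# ---------------------------------------------------------------------------
# End-to-end per-image analysis
# ---------------------------------------------------------------------------

def analyze_image(image: FundusImage,
                  mask: VesselMask | None,
                  disc: DiscGeometry,
                  config: ScanConfig = ScanConfig()) -> list[VesselMeasurement]:
    """Full pipeline on one image: enhance, scan rings, chain, measure.

    ``mask=None`` skips contrast enhancement (for images whose vessels are
    already above threshold).  Deterministic for fixed inputs.
    """
    measurements, _, _ = analyze_image_detailed(image, mask, disc, config)
    return measurements


def analyze_image_detailed(image: FundusImage,
                           mask: VesselMask | None,
                           disc: DiscGeometry,
                           config: ScanConfig = ScanConfig(),
                           ) -> tuple[list[VesselMeasurement],
                                      list[VesselChain], np.ndarray]:
    """As :func:`analyze_image`, also returning the chains and ring radii
    (needed for exports that report per-ring edge coordinates)."""
    if mask is not None:
        image = enhance_with_mask(image, mask)
    radii = ring_radii(disc, config, image_shape=image.shape)
    threshold = config.resolve_threshold(image)
    per_ring: list[list[Crossing]] = []
    for i, r in enumerate(radii):
        profile = sample_ring(image, disc.center, float(r), ring_index=i)
        try:
            per_ring.append(detect_crossings(profile, threshold))
        except NoBackgroundError as exc:
            raise NoBackgroundError(f"ring {i}: {exc}") from exc
    chains = chain_vessels(per_ring, config, inner_radius=float(radii[0]))

    if config.drop_first_ring:
        chains = [replace_rings(ch, {r: p for r, p in ch.crossings.items() if r != 0})
                  for ch in chains]
    for vid, r_min in config.inner_radius_overrides.items():
        for ch in chains:
            if ch.vessel_id == vid:
                keep = {r: p for r, p in ch.crossings.items() if radii[r] >= r_min}
                ch.crossings = keep
    chains = [ch for ch in chains if ch.n_rings > 0]

    measurements = []
    for ch in chains:
        try:
            measurements.append(measure_vessel(ch))
        except MeasurementError as exc:
            raise MeasurementError(f"vessel {ch.vessel_id}: {exc}") from exc
    return measurements, chains, radii


def replace_rings(chain: VesselChain, rings: dict) -> VesselChain:
    chain.crossings = rings
    return chain


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def measurements_to_ring_table(measurements: Sequence[VesselMeasurement],
                               chains: Sequence[VesselChain] | None = None,
                               radii: np.ndarray | None = None) -> pd.DataFrame:
    """One row per (vessel, ring): ids, radius, edge coordinates, diameter."""
    by_id = {ch.vessel_id: ch for ch in chains} if chains else {}
    rows = []
    for m in measurements:
        ch = by_id.get(m.vessel_id)
        for ring_idx, d in zip(m.ring_indices, m.diameters):
            row = {"vessel_id": m.vessel_id, "ring_index": ring_idx,
                   "radius": (float(radii[ring_idx]) if radii is not None
                              else np.nan),
                   "start_row": np.nan, "start_col": np.nan,
                   "end_row": np.nan, "end_col": np.nan,
                   "diameter_px": d}
            if ch is not None and ring_idx in ch.crossings:
                start, end = ch.crossings[ring_idx]
                row.update(start_row=start.point[0], start_col=start.point[1],
                           end_row=end.point[0], end_col=end.point[1])
            rows.append(row)
    return pd.DataFrame(rows, columns=["vessel_id", "ring_index", "radius",
                                       "start_row", "start_col", "end_row",
                                       "end_col", "diameter_px"])


def measurements_to_summary_table(measurements: Sequence[VesselMeasurement]
                                  ) -> pd.DataFrame:
    """Per-vessel summary: the CSV counterpart of a spreadsheet export."""
    return pd.DataFrame(
        [{"vessel_id": m.vessel_id, "n_rings": m.n_rings,
          "anchor_angle": m.anchor_angle, "mean": m.mean, "median": m.median,
          "sd": m.sd, "label": m.label}
         for m in measurements],
        columns=["vessel_id", "n_rings", "anchor_angle", "mean", "median",
                 "sd", "label"])
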