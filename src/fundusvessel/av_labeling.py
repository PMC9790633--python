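"""Artery/vein labeling of measured vessels.

In the mouse fundus the major arterioles and venules typically alternate
around the optic disc (reported in ~80% of C57BL/6J eyes), and venules are
wider.  With vessels ordered by angle this reduces labeling to choosing the
phase of an alternating pattern:

* ``alternate_auto`` — the widest vessel (largest mean diameter) anchors the
  "vein" phase and the pattern propagates around the circle;
* ``alternate_anchored`` — the caller pins one vessel's label and the
  pattern propagates from there;
* ``manual`` — a complete vessel_id -> label map is applied verbatim, for
  the minority of eyes that violate the alternating pattern.

With an odd number of vessels strict alternation cannot close around the
circle; the seam conflict (first and last vessel sharing a label) is
reported as a warning and labels are still assigned by propagation from the
anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import AmbiguityError, ConfigError, InputError
from .radial_scan import VesselMeasurement

ARTERY = "artery"
VEIN = "vein"
_OPPOSITE = {ARTERY: VEIN, VEIN: ARTERY}


@dataclass(frozen=True)
class LabelingPolicy:
    mode: str = "alternate_auto"  # alternate_auto | alternate_anchored | manual
    anchor_vessel_id: int | None = None
    anchor_label: str | None = None
    manual_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("alternate_auto", "alternate_anchored", "manual"):
            raise ConfigError(f"unknown labeling mode {self.mode!r}")
        if self.mode == "alternate_anchored":
            if self.anchor_vessel_id is None or self.anchor_label not in _OPPOSITE:
                raise ConfigError(
                    "alternate_anchored requires anchor_vessel_id and "
                    "anchor_label ('artery' or 'vein')")
        if self.mode == "manual" and not self.manual_labels:
            raise ConfigError("manual mode requires a complete label map")


def label_vessels(measurements: list[VesselMeasurement],
                  policy: LabelingPolicy = LabelingPolicy(),
                  ) -> list[VesselMeasurement]:
    """Assign artery/vein labels in place (and return the list).

    For the alternate modes ``measurements`` must be ordered by angle around
    the disc (the order :func:`~fundusvessel.radial_scan.analyze_image`
    produces).
    """
    if not measurements:
        raise InputError("cannot label an empty vessel list")
    n = len(measurements)

    if policy.mode == "manual":
        missing = [m.vessel_id for m in measurements
                   if m.vessel_id not in policy.manual_labels]
        if missing:
            raise ConfigError(f"manual labels missing for vessels {missing}")
        for m in measurements:
            lab = policy.manual_labels[m.vessel_id]
            if lab not in _OPPOSITE:
                raise ConfigError(f"invalid label {lab!r} for vessel {m.vessel_id}")
            m.label = lab
        return measurements

    if policy.mode == "alternate_auto":
        means = [m.mean for m in measurements]
        if n > 1 and max(means) == min(means):
            raise AmbiguityError(
                "all mean diameters equal: automatic phase anchoring is "
                "ambiguous; use alternate_anchored with an explicit anchor")
        anchor_idx = max(range(n), key=lambda i: means[i])
        anchor_label = VEIN
    else:  # alternate_anchored
        try:
            anchor_idx = next(i for i, m in enumerate(measurements)
                              if m.vessel_id == policy.anchor_vessel_id)
        except StopIteration:
            raise InputError(
                f"anchor vessel {policy.anchor_vessel_id} not in measurements"
            ) from None
        anchor_label = policy.anchor_label  # type: ignore[assignment]

    if n > 1 and n % 2 == 1:
        warnings.warn(
            f"odd vessel count ({n}): the alternating pattern cannot close "
            "around the circle; labels propagate from the anchor and the "
            "first/last neighbours share a label", stacklevel=2)
    for i, m in enumerate(measurements):
        m.label = anchor_label if (i - anchor_idx) % 2 == 0 else _OPPOSITE[anchor_label]
    return measurements
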