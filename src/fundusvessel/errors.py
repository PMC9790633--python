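"""Exception hierarchy shared across the package.

Each error class maps to a distinct CLI exit code so that batch callers can
distinguish bad inputs from bad geometry from images with no measurable
vessels.
"""

from __future__ import annotations


class FundusVesselError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(FundusVesselError):
    """Unreadable/malformed files, mismatched shapes, missing groups."""

    exit_code = 2


class FormatError(InputError):
    """Unsupported image sample format."""

    exit_code = 2


class GeometryError(FundusVesselError):
    """Disc geometry placing a sampling ring outside the image bounds."""

    exit_code = 3


class ConfigError(FundusVesselError):
    """Invalid scan/labeling/statistics configuration."""

    exit_code = 4


class NoBackgroundError(FundusVesselError):
    """A sampling ring with every sample at or above threshold: vessel edges
    cannot be delimited, typically an over-wide mask or a threshold set too
    low."""

    exit_code = 5


class NoVesselsError(FundusVesselError):
    """An analysis that produced no vessel measurements."""

    exit_code = 6


class MeasurementError(FundusVesselError):
    """A vessel chain that cannot be measured (e.g. no end points)."""

    exit_code = 5


class AmbiguityError(FundusVesselError):
    """Automatic artery/vein phase anchoring failed (all widths equal)."""

    exit_code = 5


class StatsError(FundusVesselError):
    """Group comparison preconditions violated (sample size, reference)."""

    exit_code = 4
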