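"""Exception hierarchy for the ukaspect pipeline.

Every stage raises a distinct subclass so the CLI can label which stage of
a case failed (scheme parsing, geometry, quantification, reliability,
configuration, input/output).
"""


class UkaspectError(Exception):
    """Base class for all ukaspect errors."""


class SchemeError(UkaspectError, ValueError):
    """Malformed or out-of-grammar region label, or misuse of an auxiliary region."""


class GeometryError(UkaspectError, ValueError):
    """Degenerate landmark geometry (coincident points, parallel axes, collinear fiducials)."""


class MissingLandmarkError(GeometryError, KeyError):
    """A required named landmark is absent from the landmark set."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(f"required landmark missing: {name!r}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the readable message
        return f"required landmark missing: {self.name!r}"


class QuantificationError(UkaspectError, ValueError):
    """A region box contains no voxel centers, or a statistic is undefined."""


class BackgroundError(QuantificationError):
    """Background reference is empty, zero or negative; ratios cannot be formed."""


class ReliabilityError(UkaspectError, ValueError):
    """Invalid ratings table or undefined ICC (e.g. zero total variance)."""


class ConfigError(UkaspectError, ValueError):
    """Invalid or unknown configuration keys/values."""


class VolumeError(UkaspectError, ValueError):
    """Unreadable or unsupported intensity volume (wrong dimensionality, skewed affine)."""


class PhantomError(UkaspectError, ValueError):
    """Invalid phantom specification (overlapping truth assignments, out-of-range angles)."""
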