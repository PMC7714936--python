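"""Exception hierarchy for the clearquant pipeline.

Every error raised by the library derives from :class:`ClearquantError` so
callers (and the CLI) can distinguish validation problems from genuine bugs.
"""


class ClearquantError(Exception):
    """Base class for all clearquant errors."""


class FormatError(ClearquantError):
    """An input file has an unsupported or inconsistent format."""


class AnnotationError(ClearquantError):
    """An annotation document violates the schema or an invariant."""


class BoundsError(ClearquantError):
    """A region of interest or window falls outside its image."""


class ContrastError(ClearquantError):
    """Michelson contrast is undefined (both intensities zero)."""


class SwappedRoiError(ClearquantError):
    """The light ROI is darker than the dark ROI: labels are swapped."""


class TransparencyError(ClearquantError):
    """Transparency is undefined (control contrast is zero)."""


class CohortError(ClearquantError):
    """Cohort-level inconsistency, e.g. a medulla height above the maximum."""


class DegenerateLandmarkError(ClearquantError):
    """A landmark segment has zero length."""


class NoBeadsError(ClearquantError):
    """No bead survived detection / isolation filtering."""


class EdgeBeadError(ClearquantError):
    """A profile window is clipped by the stack boundary."""


class GeometryError(ClearquantError):
    """A synthetic scene cannot be constructed with the requested geometry."""


class ConfigError(ClearquantError):
    """A pipeline configuration value is invalid."""
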