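"""Exception hierarchy.

Every error raised by the library derives from :class:`PediplanError` and
carries a short machine-parsable ``code`` used by the CLI.
"""


class PediplanError(Exception):
    """Base class for all pediplan errors."""

    code = "error"


class ConfigError(PediplanError):
    """Invalid configuration, catalog, grid or parameter range."""

    code = "config"


class GeometryInfeasibleError(PediplanError):
    """A phantom spec describes geometry that cannot be realised on a grid."""

    code = "geometry-infeasible"


class MissingStructureError(PediplanError):
    """A required anatomical label is empty in the label map."""

    code = "missing-structure"


class StructureTooSmallError(PediplanError):
    """Too few usable cross-sections to measure a structure."""

    code = "structure-too-small"


class GridTruncationError(PediplanError):
    """A ray exited the grid while still inside bone."""

    code = "grid-truncation"


class NoIntersectionError(PediplanError):
    """A ray never intersects bone."""

    code = "no-intersection"


class NotInPedicleError(PediplanError):
    """A screw cylinder does not intersect the pedicle label."""

    code = "not-in-pedicle"


class DegenerateScrewError(PediplanError):
    """A screw cylinder contains no voxel centers."""

    code = "degenerate-screw"


class OutOfGridError(PediplanError):
    """A screw lies entirely outside the image grid."""

    code = "out-of-grid"


class PlanningInfeasibleError(PediplanError):
    """No candidate trajectory satisfies all placement constraints.

    Carries the best infeasible constraint report seen during the search in
    ``best_report`` (may be None if no candidate reached constraint checking).
    """

    code = "planning-infeasible"

    def __init__(self, message, best_report=None):
        super().__init__(message)
        self.best_report = best_report


class DegenerateTestError(PediplanError):
    """A statistical test is undefined for the given sample (e.g. zero variance)."""

    code = "degenerate-test"


class PairingError(PediplanError):
    """Paired samples cannot be matched one-to-one."""

    code = "pairing"


class FormatError(PediplanError):
    """A file does not conform to the expected format or schema."""

    code = "format"
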