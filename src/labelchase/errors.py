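"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`LabelChaseError`, so callers (and the CLI) can distinguish
user/data problems from genuine bugs.
"""


class LabelChaseError(Exception):
    """Base class for all labelchase errors."""

    category = "error"


class ConfigError(LabelChaseError):
    """Invalid configuration value or combination."""

    category = "config"


class SchemaError(LabelChaseError):
    """A table or config document is missing required fields."""

    category = "schema"

    def __init__(self, message: str, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class ScheduleCoverageError(LabelChaseError):
    """A chase day falls outside the rate schedule's intervals."""

    category = "schedule"


class MissingControlError(LabelChaseError):
    """A required control population (beads, negative control) is absent."""

    category = "control"


class EmptySelectionError(LabelChaseError):
    """A summary statistic was requested on an empty event selection.

    Deliberately distinct from returning zero: "no positive events"
    must never be confused with "median intensity of zero".
    """

    category = "empty-selection"


class GeometryError(LabelChaseError):
    """Degenerate polygon, window larger than the section, etc."""

    category = "geometry"
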