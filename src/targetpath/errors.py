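"""Exception hierarchy for targetpath.

Every error raised by the library derives from :class:`TargetPathError` so
callers can catch one base class at the CLI boundary.
"""


class TargetPathError(Exception):
    """Base class for all targetpath errors."""


class SchemaError(TargetPathError):
    """A node/edge/metapath references an undeclared type, or violates the
    typed-graph schema (e.g. edge endpoints do not match the metaedge)."""


class GrammarError(TargetPathError):
    """A metapath string is lexically valid but type-incompatible."""


class MetapathParseError(TargetPathError):
    """A metapath string is malformed (dangling separator, bad alternation)."""


class FormatError(TargetPathError):
    """An input table is malformed (missing column, non-numeric field)."""


class IntegrityError(TargetPathError):
    """A graph-level referential integrity violation (edge to missing node)."""


class KGLookupError(TargetPathError, KeyError):
    """An id (node, metaedge, embedding row) is not present."""


class ConfigError(TargetPathError):
    """An invalid configuration value."""


class InputError(TargetPathError):
    """Operation preconditions on the data are not met."""


class ShapeError(TargetPathError):
    """Array dimensions are inconsistent."""


class DomainError(TargetPathError):
    """A numeric argument is outside the mathematical domain."""


class UndefinedMetricError(TargetPathError):
    """A ranking metric is undefined for the given inputs."""


class UndefinedTestError(TargetPathError):
    """A statistical test is undefined for the given inputs."""


class DependencyError(TargetPathError):
    """A pipeline stage is missing an upstream artifact."""
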