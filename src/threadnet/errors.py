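"""Exception hierarchy for threadnet.

Every error raised deliberately by the library derives from
:class:`ThreadnetError`, so callers (and the CLI) can catch one type.
"""


class ThreadnetError(Exception):
    """Base class for all threadnet errors."""


class SchemaError(ThreadnetError):
    """An input file does not conform to the post-log schema
    (missing column, unknown role, unparseable timestamp, unknown format)."""


class DanglingReferenceError(ThreadnetError):
    """A post references a parent_post_id that does not exist in the log."""


class ConsistencyError(ThreadnetError):
    """A post's stored hierarchy level disagrees with its parent chain."""


class ConfigError(ThreadnetError):
    """A configuration is invalid or infeasible (e.g. an expected event
    count too small to realize the requested community)."""


class ParameterError(ThreadnetError):
    """A function was called with an out-of-range or unknown parameter."""


class EmptyInputError(ThreadnetError):
    """An operation that needs data received an empty input
    (empty graph, no user with two or more posts, ...)."""


class InsufficientDataError(ThreadnetError):
    """A statistical summary was requested on too few usable records."""
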