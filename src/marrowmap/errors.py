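"""Exception hierarchy shared by all pipeline stages.

Exit codes (used by the CLI) distinguish the three failure families the
pipeline can hit: malformed input tables, infeasible synthetic placement,
and statistically degenerate data.
"""


class MarrowError(Exception):
    """Base class for all marrowmap errors."""

    exit_code = 1


class SchemaError(MarrowError):
    """An input table violates the expected dialect (columns, types, ids)."""

    exit_code = 2


class PlacementError(MarrowError):
    """The synthetic generator cannot satisfy a placement constraint."""

    exit_code = 3


class EmptyTargetError(MarrowError):
    """A distance query was made against an empty target class."""

    exit_code = 4


class DegenerateDataError(MarrowError):
    """A statistical routine received data it cannot test (e.g. empty margin)."""

    exit_code = 5


class ConfigError(MarrowError):
    """A generator or pipeline configuration value is invalid."""

    exit_code = 2
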