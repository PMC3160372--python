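"""Exception hierarchy shared across the package."""


class RcrnetError(Exception):
    """Base class for all rcrnet errors."""


class GraphParseError(RcrnetError):
    """A graph file could not be parsed; names the offending row/field."""

    def __init__(self, message, row=None, field=None):
        self.row = row
        self.field = field
        where = []
        if row is not None:
            where.append(f"row {row}")
        if field is not None:
            where.append(f"field {field!r}")
        suffix = f" ({', '.join(where)})" if where else ""
        super().__init__(f"{message}{suffix}")


class VocabularyError(GraphParseError):
    """A value falls outside a closed controlled vocabulary."""


class ReferentialError(GraphParseError):
    """An edge endpoint does not resolve to a declared node."""


class UnknownNodeError(RcrnetError, KeyError):
    """A node id was looked up that does not exist in the graph."""


class ContractError(RcrnetError, ValueError):
    """Arguments violate a documented pre-condition."""


class ConfigError(RcrnetError, ValueError):
    """A configuration object is internally inconsistent."""


class StageError(RcrnetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")
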