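"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`AirrprofError`, so callers (and the CLI) can separate data/contract
problems from genuine bugs.
"""


class AirrprofError(Exception):
    """Base class for all errors raised by airrprof."""


class SchemaError(AirrprofError):
    """An input table is missing a required (mapped) column."""


class FieldParseError(AirrprofError):
    """A cell could not be parsed; message names the row and offending value."""


class ContractError(AirrprofError):
    """A caller violated an operation's input contract."""


class IncompatibleDefinitionError(AirrprofError):
    """The clonotype definition lacks a component the operation needs,
    or is not eligible for a comparison operation."""


class UnsupportedSubgroupError(AirrprofError):
    """A gene subgroup outside {V, J} (notably D) was requested."""


class ConfigError(AirrprofError):
    """A simulation or filter configuration is unsatisfiable."""
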