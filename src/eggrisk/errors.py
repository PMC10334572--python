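"""Exception hierarchy used across the package.

All errors raised intentionally by eggrisk derive from :class:`EggRiskError`
so callers (and the CLI) can distinguish validation problems from bugs.
"""


class EggRiskError(Exception):
    """Base class for all eggrisk errors."""


class SchemaError(EggRiskError):
    """An input table is missing required columns or has the wrong layout."""


class ValidationError(EggRiskError):
    """A value violates a contract (negative concentration, bad parameter...)."""


class PairingError(EggRiskError):
    """Paired seasonal units cannot be matched one-to-one."""


class DegenerateDataError(EggRiskError):
    """Too little data, or zero variance where a test requires spread."""


class ConfigError(EggRiskError):
    """A configuration object or file is inconsistent or incomplete."""
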