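"""Exception hierarchy.

Config errors (bad keys, malformed specs) and data errors (incomplete
cohorts, unusable inputs) are kept distinct so the command-line layer can
map them to different exit codes.
"""


class HepvolError(Exception):
    """Base class for all package errors."""


class ConfigError(HepvolError):
    """Invalid configuration: unknown keys, out-of-range parameters."""


class InfeasibleSpecError(ConfigError):
    """A phantom spec whose constraints cannot be satisfied jointly."""


class DataError(HepvolError):
    """Invalid or incomplete input data."""


class IncompleteCohortError(DataError):
    """A cohort missing required subject/observer combinations."""
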