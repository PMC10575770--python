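"""Exception hierarchy shared across the package."""


class FamsegError(Exception):
    """Base class for all package errors."""


class InputError(FamsegError):
    """Malformed or inconsistent user input (tables, VCF, config values)."""


class ConfigError(FamsegError):
    """Missing or invalid configuration (e.g. absent instrument norms)."""


class PedigreeError(FamsegError):
    """Structural pedigree problem: dangling parent, duplicate id, cycle."""


class UndefinedTestError(FamsegError):
    """A statistic is undefined for the given table (e.g. zero margin)."""


class SimulationError(FamsegError):
    """The synthetic-cohort generator could not satisfy a planting constraint."""
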