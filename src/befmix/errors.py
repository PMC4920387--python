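"""Exception hierarchy for befmix."""


class BefmixError(Exception):
    """Base class for all befmix errors."""


class DesignError(BefmixError):
    """The experimental design or species metadata is malformed."""


class SchemaError(BefmixError):
    """An input table does not match its documented schema."""


class TableValidationError(BefmixError):
    """A biomass table contains hard violations against the design."""


class MissingReferenceError(BefmixError):
    """No monoculture reference exists for a species x environment."""


class UndefinedRelativeYieldError(BefmixError):
    """A relative yield is undefined (zero monoculture biomass)."""


class PartitionUndefinedError(BefmixError):
    """The tripartite partition is undefined (e.g. all species dead)."""


class GeneratorError(BefmixError):
    """A generator configuration is invalid or produces impossible data."""


class ConfigError(BefmixError):
    """A pipeline configuration file is invalid."""
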