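"""Exception hierarchy for the ETSM pipeline."""


class EtsmError(Exception):
    """Base class for all package errors."""


class SchemaError(EtsmError):
    """An input table is missing a required column or has an unusable dtype."""


class IntegrityError(EtsmError):
    """Cross-table referential or window constraint violated."""


class ConfigurationError(EtsmError):
    """A configuration value is invalid or infeasible."""


class UnlabelableError(EtsmError):
    """A patient record carries no creatinine series, so no KDIGO label exists."""


class ProtocolError(EtsmError):
    """The evaluation protocol cannot run (e.g. a class with < 2 samples)."""


class UndefinedMetricError(EtsmError):
    """A metric is undefined for the given predictions (e.g. one class absent)."""


class MissingArtifactError(EtsmError):
    """A CLI stage requires an artifact that an earlier stage has not produced."""
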