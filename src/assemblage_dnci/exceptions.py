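"""Exception hierarchy for the assemblage-dnci package."""


class AssemblageError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AssemblageError):
    """A file does not conform to the expected CSV dialect."""


class ValidationError(AssemblageError):
    """Data violate a structural invariant (domain, labels, metadata)."""


class ConfigurationError(AssemblageError):
    """A parameter, predicate or config entry is out of contract."""


class DegenerateConfigurationError(ConfigurationError):
    """A simulation config would produce an essentially empty matrix."""


class InsufficientDataError(AssemblageError):
    """Too few sampling units for the requested statistic."""


class UndefinedRatioError(AssemblageError):
    """Ratio of counts with a zero denominator."""


class UndefinedDNCIError(AssemblageError):
    """DNCI undefined, e.g. the empirical overall dissimilarity is zero."""


class AnalysisNotPossibleError(AssemblageError):
    """A pipeline stage cannot run (e.g. <2 clusters after removal)."""
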