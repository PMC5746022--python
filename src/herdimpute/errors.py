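"""Exception hierarchy shared across the package."""


class HerdimputeError(Exception):
    """Base class for all herdimpute errors."""


class FormatError(HerdimputeError):
    """Malformed or unsupported input file content."""


class DuplicateSiteError(FormatError):
    """Two records share the same (chrom, pos)."""


class MissingSiteError(HerdimputeError):
    """A requested site is absent from the available site list."""


class AlignmentError(HerdimputeError):
    """Two matrices do not share the samples/sites an operation requires."""


class IncomparablePairError(HerdimputeError):
    """A pair of samples has no shared non-missing loci."""


class DegenerateWindowError(HerdimputeError):
    """A phasing window contains no usable genotype information."""


class ConstraintError(HerdimputeError):
    """A clustering size constraint cannot be satisfied."""


class ParameterError(HerdimputeError):
    """An argument value is outside its valid range."""


class ConfigError(HerdimputeError):
    """An experiment or simulation configuration is inconsistent."""


class AssemblyError(HerdimputeError):
    """Feature-table assembly found animals missing from an input source."""


class SingularDesignError(HerdimputeError):
    """The regression design matrix is rank deficient after level dropping."""


class PredictionError(HerdimputeError):
    """Prediction requested for data the fitted model cannot score."""
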