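"""Exception hierarchy for haplasso."""


class HaplassoError(Exception):
    """Base class for all package errors."""


class ConfigError(HaplassoError):
    """Invalid configuration value (unknown mode, bad key, ...)."""


class DataError(HaplassoError):
    """Input data violate a structural requirement."""


class MendelianInconsistencyError(DataError):
    """A trio's genotypes admit no Mendelian transmission."""


class MissingnessError(DataError):
    """A genotype vector exceeds the per-subject missing-SNP cap."""


class ImpossibleStateError(HaplassoError):
    """A phase assignment has zero probability under current parameters."""


class AdjustmentError(HaplassoError):
    """The magnitude adjustment could not be computed (degenerate H or J)."""


class SimulationError(HaplassoError):
    """Rejection sampling exhausted its draw budget."""
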