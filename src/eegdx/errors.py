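"""Exception hierarchy shared by all eegdx modules."""


class EegdxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EegdxError):
    """Malformed input file (bad line, unsupported layout, empty file)."""


class ParameterError(EegdxError, ValueError):
    """A user-supplied parameter is out of its valid range."""


class ContractError(EegdxError, ValueError):
    """Two objects passed together violate a mutual precondition
    (e.g. sampling-rate or dimensionality mismatch)."""


class DesignError(EegdxError, ValueError):
    """A filter cannot be realized with the requested parameters."""


class DomainError(EegdxError, ValueError):
    """A statistic was requested on input outside its domain
    (empty, all-zero, or degenerate sequence)."""


class ConvergenceError(EegdxError, RuntimeError):
    """An iterative decomposition failed to converge after retry."""


class TrainingError(EegdxError, ValueError):
    """Classifier training input is unusable (single class, non-finite)."""


class FoldError(EegdxError, ValueError):
    """A cross-validation partition cannot be constructed."""


class ConfigError(EegdxError, ValueError):
    """A pipeline configuration references an unknown component."""
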