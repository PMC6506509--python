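"""Exception hierarchy shared across the pipeline."""


class SchetError(Exception):
    """Base class for all package errors."""


class FormatError(SchetError):
    """A file could not be parsed in the requested format (missing sidecars, bad header, ...)."""


class ValidationError(SchetError):
    """Input data violates an invariant (negative counts, duplicate ids, shape mismatch)."""


class ConfigError(SchetError):
    """A pipeline or generator configuration parameter is out of its allowed range."""


class EstimationError(SchetError):
    """A statistical estimate cannot be formed (no reference genes, rank-deficient design, ...)."""


class GeneSetError(SchetError):
    """A gene set cannot be resolved against the expression matrix."""


class PipelineError(SchetError):
    """A pipeline stage failed; the message names the stage."""
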