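"""Exception hierarchy for the benchmark suite."""


class CommbenchError(Exception):
    """Base class for all package-specific errors."""


class InvalidConditionError(CommbenchError, ValueError):
    """A simulation condition is internally inconsistent or infeasible."""


class GenerationError(CommbenchError, RuntimeError):
    """Synthetic data generation failed (non-PSD model, wiring budget, ...)."""


class DegenerateInputError(CommbenchError, ValueError):
    """A matrix is unusable for detection (e.g. all zero after clipping)."""


class UndefinedMetricError(CommbenchError, ValueError):
    """A score is undefined for the given inputs (e.g. zero true modularity)."""
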