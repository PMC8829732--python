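"""Exception types shared across the package."""


class PregstratError(Exception):
    """Base class for all package errors."""


class CohortStructureError(PregstratError):
    """The input panel violates the delivery-interruption data structure."""


class PositivityError(PregstratError):
    """A required conditional probability is degenerate (0 or 1) for
    subjects who need a finite inverse-probability weight."""


class EstimationError(PregstratError):
    """An estimator could not be computed on the given cohort."""


class ConvergenceError(EstimationError):
    """An iterative fit (e.g. the TMLE fluctuation) failed to converge."""
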