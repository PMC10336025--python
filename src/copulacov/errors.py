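"""Exception types shared across the package."""


class InsufficientDataError(ValueError):
    """Raised when a dataset violates an identifiability floor.

    The three parameters of a zero-inflated beta margin need at least three
    nonzero observations; pair-level estimation additionally needs at least
    two jointly nonzero observations.
    """


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge.

    Carries the last iterate in ``last_params`` for diagnostics.
    """

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class DegenerateDataError(ValueError):
    """Raised when data admit no informative fit (e.g. all observations at the atom)."""


class SimulationDegenerateError(RuntimeError):
    """Raised when the simulator exhausts its redo budget on a degenerate configuration."""
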