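"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract (shapes, ranges, frames)."""


class ConfigurationError(ValueError):
    """Raised when a simulation setup is inconsistent (missing wrapper, bad tag...)."""


class StabilityError(RuntimeError):
    """Raised when the explicit scheme produces non-finite state values.

    Carries the step index and the CFL bound so the caller can diagnose
    whether the chosen time step exceeded the stable range.
    """

    def __init__(self, message: str, step: int | None = None,
                 cfl_bound: float | None = None):
        super().__init__(message)
        self.step = step
        self.cfl_bound = cfl_bound
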