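"""Exception hierarchy.

Validation errors (bad inputs, bad configuration) map to CLI exit code 2;
computation errors (registration failure, non-convergent fits) to exit code 3.
"""


class SevquantError(Exception):
    """Base class for all package errors."""


class ValidationError(SevquantError, ValueError):
    """Invalid input data or configuration."""


class DensityError(ValidationError):
    """Particle density too high for well-posed single-particle counting."""


class ComputationError(SevquantError, RuntimeError):
    """A computation failed in a way that should not be silently ignored."""


class RegistrationError(ComputationError):
    """Image registration could not be trusted (correlation below floor)."""


class FitError(ComputationError):
    """A model fit failed or produced a non-physical result."""
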