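"""Exception hierarchy shared across the package."""


class TrophontError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TrophontError, ValueError):
    """An input violated a documented precondition or schema."""


class EmptyStomachError(TrophontError):
    """Raised when a diet operation is asked to normalize an empty stomach.

    Empty stomachs carry no diet information; callers catch this signal and
    exclude the individual from the diet matrix and from prevalence
    denominators.
    """


class UnmappedPreyError(ValidationError):
    """A raw prey label has no entry in the prey-category map."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(f"unmapped prey label: {label!r}")


class DegenerateBaselineError(ValidationError):
    """Littoral and pelagic end-members too close in d13C to mix against."""


class DegenerateClassesError(TrophontError):
    """Logistic fit requested but only one response class is present.

    Trout-only communities produce all-zero piscivory flags, for which a
    size-at-piscivory curve is undefined.
    """


class SeparationError(TrophontError):
    """Complete or quasi-complete separation in a logistic fit."""

    def __init__(self, message: str, boundary: float | None = None):
        self.boundary = boundary
        super().__init__(message)


class ConvergenceError(TrophontError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        self.trace = trace
        super().__init__(message)
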