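"""Exception hierarchy for the vesicle density model."""


class VesidensError(Exception):
    """Base class for all package-specific errors."""


class InvariantError(VesidensError, ValueError):
    """A domain type was constructed with values violating its invariants."""


class DegenerateSystemError(VesidensError, ValueError):
    """The simultaneous density equations are degenerate and cannot be solved.

    Raised when the treatment removes nothing (M = 1, so pre- and
    post-treatment equations coincide) or when the sensitive-component
    density equals the post-treatment density (division by zero in the
    closed-form inversion).
    """


class InfeasibleMeasurementError(VesidensError, ValueError):
    """Measurements are incompatible with the two-component mixture model.

    The inversion produced a volume fraction outside [0, 1]; the message
    names the feasible measurement range so the experimenter can see which
    input is out of bounds.
    """
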