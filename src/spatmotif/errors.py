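"""Exception hierarchy for spatmotif."""


class SpatmotifError(Exception):
    """Base class for all package errors."""


class SizingError(SpatmotifError):
    """Grid too small or otherwise degenerate for the finite-difference stencil."""


class ShapeError(SpatmotifError):
    """A field does not match the domain (or another field) it is bound to."""


class SignalValidityError(SpatmotifError):
    """A signal specification produces negative concentrations."""


class ConfigurationError(SpatmotifError):
    """Invalid model/run configuration (missing or unknown parameter, key, motif)."""


class ValidityError(SpatmotifError):
    """A closed-form reduction is used outside its domain of validity."""


class KineticsError(SpatmotifError):
    """Degenerate kinetics (zero denominators, no real fixed point, ...)."""


class RegistryError(SpatmotifError):
    """Unknown scenario or registry id."""


class NonConvergenceError(SpatmotifError):
    """Time integration failed; carries the last valid state when available."""

    def __init__(self, message, last_state=None, t=None):
        super().__init__(message)
        self.last_state = last_state
        self.t = t


class CalibrationError(SpatmotifError):
    """A fixture parameter set fails its required dynamical regime."""
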