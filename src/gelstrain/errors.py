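"""Exception hierarchy for gelstrain.

Errors are grouped by origin: bad configuration, bad data values, and
numerical/geometric failures, so the CLI can map them to exit codes.
"""


class GelstrainError(Exception):
    """Base class for all package errors."""


class ConfigError(GelstrainError):
    """Malformed configuration or input file."""


class DataError(GelstrainError, ValueError):
    """Input values violate a documented precondition."""


class NumericalError(GelstrainError):
    """A solver or fit failed to produce a usable result."""


class NoCrossover(NumericalError):
    """G' - G'' does not change sign anywhere in the sampled sweep."""


class MultipleCrossovers(NumericalError):
    """G' - G'' changes sign more than once; all brackets are reported."""

    def __init__(self, brackets):
        self.brackets = list(brackets)
        super().__init__(
            f"{len(self.brackets)} sign changes of G'-G'' found at "
            f"frequency brackets (Hz): {self.brackets}"
        )


class DegenerateRelaxation(NumericalError):
    """Relaxation data do not decay; an exponential-sum fit is meaningless."""


class FitError(NumericalError):
    """Least-squares fit failed to converge."""


class ConstructionError(NumericalError):
    """A Maxwell spectrum matching the requested gel point cannot be built."""


class UnachievableFrequency(DataError):
    """Requested heart-rate band lies outside the calibrated f_GP range."""


class UnachievableModulus(DataError):
    """Requested gel-point modulus lies outside the tunable range."""


class ExtrapolationWarning(UserWarning):
    """A formulation lies outside the calibration knot hull."""


class GeometryError(GelstrainError):
    """Contour geometry violates an assumption (containment, centroid, ...)."""


class NonStarShaped(GeometryError):
    """A sector-boundary ray intersects the contour more than once."""
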