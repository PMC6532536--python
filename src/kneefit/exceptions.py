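"""Exception hierarchy."""


class KneefitError(Exception):
    """Base class for all package-specific errors."""


class ParameterDomainError(KneefitError, ValueError):
    """A model parameter violates its domain (e.g. non-positive slope)."""


class DataFormatError(KneefitError, ValueError):
    """An input file or in-memory container violates its format contract."""


class MissingNoiseDataError(KneefitError, ValueError):
    """No no-stimulus data from which to estimate the noise floor.

    The noise level sigma is never fitted; it must be measured from a
    recording without stimulation (or, for spike data, from the
    spontaneous-activity window) and held fixed during fitting.
    """


class TooFewPointsError(KneefitError, ValueError):
    """Not enough level-response points to constrain the model fit."""


class CriterionError(KneefitError, ValueError):
    """A threshold criterion was applied outside its domain."""
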