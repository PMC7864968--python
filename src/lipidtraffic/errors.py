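"""Exception types shared across the package."""


class LipidTrafficError(Exception):
    """Base class for all package errors."""


class LipidNameError(LipidTrafficError, ValueError):
    """A lipid shorthand name could not be parsed."""


class DataError(LipidTrafficError, ValueError):
    """An input table violates an invariant (negative cell, missing metadata...)."""


class NetworkError(LipidTrafficError, ValueError):
    """A compartment network is malformed or an axis is unknown."""


class UndefinedStatisticError(LipidTrafficError, ValueError):
    """A statistic is undefined for the given inputs (e.g. Jaccard of two
    empty sets, ENFC with a zero group mean); carries a human-readable reason."""
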