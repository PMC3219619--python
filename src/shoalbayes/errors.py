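"""Exception types shared across the package."""


class ShoalBayesError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ShoalBayesError, ValueError):
    """A model parameter is outside its valid domain (e.g. non-positive)."""


class InvalidInputError(ShoalBayesError, ValueError):
    """An input value (counts, probabilities, bins) is malformed."""


class SchemaError(ShoalBayesError, ValueError):
    """A file or record does not conform to the expected schema."""


class CapacityError(ShoalBayesError, ValueError):
    """A request exceeds the exact-enumeration size limits."""


class InfiniteReliabilityError(ShoalBayesError, ZeroDivisionError):
    """A reliability ratio is infinite (zero error probability)."""
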