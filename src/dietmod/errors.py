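"""Exception hierarchy for the diet-modeling pipeline."""


class DietmodError(Exception):
    """Base class for all package errors."""


class InputValidationError(DietmodError, ValueError):
    """Malformed or out-of-range user input (negative grams, bad spec...)."""


class InvalidReferenceError(DietmodError, ValueError):
    """Non-positive or inconsistent dietary-reference values."""


class ReferenceLookupError(DietmodError, KeyError):
    """Unknown nutrient or out-of-range age/sex in a reference lookup."""


class UnknownFoodError(DietmodError, KeyError):
    """Recall rows reference food codes absent from the composition table."""


class CompositionError(DietmodError, ValueError):
    """Inconsistent or missing food/milk composition data."""
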