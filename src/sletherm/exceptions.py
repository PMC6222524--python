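"""Exception hierarchy for solubility data handling and model evaluation."""


class SolubilityError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SolubilityError, ValueError):
    """A domain invariant was violated (non-physical temperature, x outside (0,1), ...)."""


class FormatError(SolubilityError, ValueError):
    """A file or stream could not be parsed as solubility data."""


class LookupDataError(SolubilityError, KeyError):
    """An unknown built-in dataset or descriptor was requested."""


class ModelDomainError(SolubilityError, ValueError):
    """Model parameters put the evaluation outside the model's domain
    (e.g. a non-positive Wilson Lambda at a dataset temperature)."""


class GenerationError(SolubilityError, ValueError):
    """Synthetic-data generation produced a non-physical mole fraction."""
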