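"""Exception hierarchy.

All package errors derive from :class:`RutfError` so callers can catch one
base class; subclasses distinguish configuration, data, and solver failures
(the CLI maps them to distinct exit codes).
"""


class RutfError(Exception):
    """Base class for all rutfopt errors."""


class ConfigError(RutfError):
    """Invalid run configuration (missing file, bad year range, bad option)."""


class SchemaError(RutfError):
    """A table is missing a required column or nutrient key."""


class DataValidationError(RutfError):
    """A value violates a domain invariant (negative nutrient, bad sum...)."""


class EmptyTableError(RutfError):
    """A loaded table contains no usable rows."""


class FormulationImbalanceError(DataValidationError):
    """Formulation percentages do not sum to 100 within tolerance."""

    def __init__(self, name: str, total: float):
        self.name = name
        self.total = total
        super().__init__(
            f"formulation {name!r}: percentages sum to {total:.4f}, expected 100"
        )


class UnknownIngredientError(DataValidationError):
    """A formulation references an ingredient absent from the ingredient set."""


class BasisError(DataValidationError):
    """Profiles on mixed bases (as-is vs dry) were combined."""


class MissingPriceError(RutfError):
    """No price available for an (ingredient, year) cell; never interpolated."""


class InfeasibleCompositionError(DataValidationError):
    """Proximate components sum to more than 100 g per 100 g."""


class KeyMismatchError(SchemaError):
    """Predicted and actual profiles cover different nutrient keys."""


class UnmeetableRequirementError(RutfError):
    """A required nutrient has zero density: no intake can meet it."""


class SolverError(RutfError):
    """The LP solver failed numerically; carries solver diagnostics."""


class PlantingError(RutfError):
    """Planted-optimum construction failed its uniqueness certification."""


class ComplexityError(RutfError):
    """Brute-force enumeration requested over too many free ingredients."""
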