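"""Exception hierarchy shared across the pipeline stages."""


class SoacmlError(Exception):
    """Base class for all package-specific errors."""


class SpecValidationError(SoacmlError, ValueError):
    """A configuration or synthetic-data spec violates an invariant.

    Carries ``field`` naming the violated field so callers (and the CLI)
    can point at the offending entry.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class SchemaError(SoacmlError, ValueError):
    """An input table is missing required columns or is otherwise malformed."""


class CapabilityError(SoacmlError, RuntimeError):
    """A requested backend or optional library is not available.

    Never raised silently: the missing capability is named so a run can
    either abort (featurization backends) or continue with the remaining
    algorithms (model suite), logging the gap.
    """

    def __init__(self, capability: str, message: str):
        self.capability = capability
        super().__init__(f"capability '{capability}' unavailable: {message}")


class FeaturizationError(SoacmlError, ValueError):
    """A single compound could not be featurized (e.g. unparsable SMILES)."""
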