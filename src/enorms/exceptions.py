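"""Exception hierarchy.

All package errors derive from :class:`ENormsError` so callers can catch one
base class; the leaf classes mirror the distinct failure modes of the
pipeline (bad schema, too little data, no detectable plateau, rater-protocol
violations, invalid configuration).
"""


class ENormsError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(ENormsError):
    """An input table is missing a mapped column or has an unusable layout."""


class EmptyInputError(ENormsError):
    """An input file or value set contained no usable rows."""


class ConfigError(ENormsError):
    """Invalid run configuration (overlapping strata, bad parameters...)."""


class InsufficientDataError(ENormsError):
    """Too few observations for the requested operation."""


class InsufficientSampleError(InsufficientDataError):
    """A group failed the minimum-n gate; carries the observed n."""

    def __init__(self, n: int, min_n: int):
        self.n = int(n)
        self.min_n = int(min_n)
        super().__init__(
            f"group has n={n} observations; more than {min_n} are required"
        )


class NoPlateauError(ENormsError):
    """No rank window satisfied the plateau tolerance."""


class ProtocolError(ENormsError):
    """Rater-protocol violation (mismatched curves, unknown rater id)."""


class ContractError(ENormsError):
    """A documented precondition was violated by the caller."""


class UndefinedRatioError(ENormsError):
    """Abnormality ratio is undefined (traditional percentage is zero)."""
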