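"""Exception hierarchy shared across the package."""


class SurfconsError(Exception):
    """Base class for all package errors."""


class FormatError(SurfconsError):
    """A file could not be parsed (malformed record, ragged alignment, ...)."""


class EmptyInputError(SurfconsError):
    """An input was syntactically valid but contained no usable data."""


class LookupFailure(SurfconsError):
    """A required key (chain, radius, reference value, tree tip) was absent."""


class ParameterError(SurfconsError):
    """A numeric/config parameter was outside its allowed domain."""


class IdentityMismatchError(SurfconsError):
    """The structure residue at a mapped variant position does not match the
    recorded wild type.  Raised hard: silent misnumbering is the classic
    failure mode when joining variant tables to structures."""

    def __init__(self, variant_id, expected, found, residue):
        self.expected = expected
        self.found = found
        self.residue = residue
        super().__init__(
            f"variant {variant_id}: structure residue {residue} is {found}, "
            f"variant table says wild type {expected}"
        )


class GenerationError(SurfconsError):
    """A synthetic-data generator could not satisfy its constraints."""


class ConfigError(SurfconsError):
    """A pipeline run configuration failed validation."""


class DataError(SurfconsError):
    """A pipeline stage failed on its input data."""
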