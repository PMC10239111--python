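"""Exception hierarchy shared across the package."""


class StrataforgeError(Exception):
    """Base class for all package errors."""


class ParameterError(StrataforgeError, ValueError):
    """An argument is outside its documented domain."""


class ParseError(StrataforgeError):
    """A genotype or table file could not be parsed."""


class EmptyInputError(StrataforgeError):
    """An input file or matrix contains no usable records."""


class EmptyResultError(StrataforgeError):
    """A filter or analysis removed every record."""


class AlleleMismatchError(StrataforgeError):
    """REF/ALT alleles disagree between a fitted model and new genotypes."""
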