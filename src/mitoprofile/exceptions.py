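"""Exception hierarchy shared across the package."""


class MitoprofileError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(MitoprofileError, ValueError):
    """A position falls outside the 1..16,569 mitochondrial coordinate range."""


class UnknownFeatureError(MitoprofileError, KeyError):
    """A feature name is not present in the gene map."""


class ValidationError(MitoprofileError, ValueError):
    """Input values violate a documented contract."""


class FormatError(MitoprofileError, ValueError):
    """A file does not conform to the expected format."""


class ReferenceMismatchError(MitoprofileError, ValueError):
    """A stated reference base disagrees with the reference sequence."""


class NonCodingPositionError(MitoprofileError, ValueError):
    """Codon-level effect requested for a position outside protein genes."""


class MissingNormalError(ValidationError):
    """Somatic calling was attempted without a matched normal profile."""
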