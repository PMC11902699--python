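"""Exception types raised across the package."""


class EmptyPoolError(ValueError):
    """Raised when an operation requires a non-empty labeled or unlabeled pool."""


class MissingMappingError(KeyError):
    """Raised when a fine-grained class has no entry in a coarse-graining map."""


class InvalidQueryError(ValueError):
    """Raised when the oracle is asked to label an index outside the unlabeled pool."""
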