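"""Exception hierarchy shared across the package."""


class BacpromError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(BacpromError):
    """Malformed FASTA input (missing header, illegal residue, ...)."""


class AnnotationFormatError(BacpromError):
    """Annotation table missing mandatory columns or otherwise unparseable."""


class CatalogIntegrityError(BacpromError):
    """The packaged sigma-factor catalog failed its integrity checks."""


class CapacityError(BacpromError):
    """A sampling or packing request cannot be satisfied.

    Carries ``achievable``, the largest feasible count, when known.
    """

    def __init__(self, message: str, achievable: int | None = None):
        super().__init__(message)
        self.achievable = achievable


class GridSpecError(BacpromError):
    """Invalid hyperparameter grid specification."""


class EncodingError(BacpromError):
    """A sequence cannot be encoded under the requested scheme."""


class EncodingMismatchError(BacpromError):
    """Model and input were produced under different feature encodings."""
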