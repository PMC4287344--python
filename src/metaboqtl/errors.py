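"""Exception types shared across the package."""


class MetaboqtlError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(MetaboqtlError, ValueError):
    """An argument is outside its documented domain."""


class PedigreeError(MetaboqtlError, ValueError):
    """Structurally invalid pedigree (cycles, missing parents, bad links)."""


class InsufficientDataError(MetaboqtlError, ValueError):
    """Too few non-missing observations for the requested operation."""


class DegenerateDesignError(MetaboqtlError, ValueError):
    """Rank-deficient or otherwise unidentifiable design."""


class UndefinedLDError(MetaboqtlError, ValueError):
    """LD is undefined because a genotype vector is constant."""


class MatrixError(MetaboqtlError, ValueError):
    """A covariance-structure matrix fails its requirements (e.g. not PSD)."""


class UndefinedRatioError(MetaboqtlError, ZeroDivisionError):
    """A variance ratio is requested with zero total variance."""
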