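"""Exception hierarchy shared across the package."""


class RxnMetricError(Exception):
    """Base class for all package-specific errors."""


class MoleculeParseError(RxnMetricError):
    """SMILES or mol-block text could not be parsed."""


class ReactionValidationError(RxnMetricError):
    """Reaction violates a structural requirement (e.g. empty side)."""


class AtomMappingError(RxnMetricError):
    """Atom-map numbers are inconsistent, duplicated, or missing."""


class ConfigError(RxnMetricError):
    """Invalid run configuration or input table layout."""


class FingerprintMismatchError(RxnMetricError):
    """Two fingerprints of different type or length were compared."""


class UnknownMeasureError(RxnMetricError):
    """Similarity measure name is not one of the supported identifiers."""


class UnsupportedElementError(RxnMetricError):
    """Element outside the bundled parameter tables."""


class UndefinedCorrectionError(RxnMetricError):
    """Property correction requested with zero paired molecules."""


class IncompleteECError(RxnMetricError):
    """EC string has fewer fields than the comparison level."""


class DegenerateLabelsError(RxnMetricError):
    """ROC input contains a single class only."""
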