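"""Error taxonomy.

Every exception carries a short machine-readable ``code`` so the CLI can map
failures onto stable exit diagnostics.
"""

from __future__ import annotations


class OtlocError(Exception):
    """Base class for all package errors."""

    code: str = "otloc-error"

    def __init__(self, message: str = ""):
        super().__init__(message or self.code)


class IncompleteLeadsError(OtlocError):
    code = "incomplete-leads"


class RaggedRecordError(OtlocError):
    code = "ragged-record"


class BadRateError(OtlocError):
    code = "bad-rate"


class BadWaveletError(OtlocError):
    code = "bad-wavelet"


class TooShortError(OtlocError):
    code = "too-short"


class FlatSignalError(OtlocError):
    code = "flat-signal"


class WindowOutOfRangeError(OtlocError):
    code = "window-out-of-range"


class UnknownCriterionError(OtlocError):
    code = "unknown-criterion"


class DegenerateCohortError(OtlocError):
    code = "degenerate-cohort"


class BadFeaturesError(OtlocError):
    code = "bad-features"


class NoInformativeFeaturesError(OtlocError):
    code = "no-informative-features"


class DegenerateValidationError(OtlocError):
    code = "degenerate-validation"


class MissingFeatureError(OtlocError):
    code = "missing-feature"


class DegenerateLabelsError(OtlocError):
    code = "degenerate-labels"


class UnpairedScoresError(OtlocError):
    code = "unpaired-scores"


class BadPvcPositionError(OtlocError):
    code = "bad-pvc-position"
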