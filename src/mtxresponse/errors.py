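"""Exception hierarchy for the response-analysis pipeline.

All errors derive from :class:`MtxResponseError` so callers can catch the
package's failures in one clause; the leaves distinguish validation,
window-coverage, and undefined-statistic failures.
"""


class MtxResponseError(ValueError):
    """Base class for all package errors."""


class ValidationError(MtxResponseError):
    """An input value violates a documented domain constraint."""


class CoverageError(MtxResponseError):
    """A patient's visits or dose intervals do not cover an analysis window."""


class ZeroDoseError(MtxResponseError):
    """Cumulative dose is zero, so the dose-normalized index is undefined."""


class IndeterminateControlError(MtxResponseError):
    """No visits fall inside the disease-control window; no label can be given."""


class GenotypeParseError(MtxResponseError):
    """A genotype string or SNP name could not be interpreted."""


class CohortJoinError(MtxResponseError):
    """Patient identifiers do not line up across tables that must be joined."""
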