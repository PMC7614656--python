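"""Typed exceptions shared across the package.

Degenerate probability configurations raise errors rather than propagating
infinities or NaNs, so that downstream bias surfaces and simulation summaries
never silently contain corrupt cells.
"""


class CompmiError(Exception):
    """Base class for all package errors."""


class DomainError(CompmiError, ValueError):
    """An input value is outside its mathematical domain (e.g. a negative
    probability, a non-binary component value)."""


class DegenerateOddsError(CompmiError, ZeroDivisionError):
    """An odds or odds-ratio is requested but a required cell probability is
    zero, so the odds are 0 or infinite."""


class UndefinedConditionalError(CompmiError, ZeroDivisionError):
    """A conditional probability is requested given an event of probability
    zero."""


class CalibrationError(CompmiError, RuntimeError):
    """A root-finding calibration failed; the message reports the achievable
    range of the target quantity."""


class SeparationError(CompmiError, RuntimeError):
    """A logistic fit encountered perfect prediction (separation): the
    maximum-likelihood estimate is infinite.  Use pseudo-observation
    augmentation to obtain a finite fit."""


class DegenerateStratumError(SeparationError):
    """A stratified imputation model has a stratum with no fitting rows or an
    outcome-invariant fitting set."""


class EmptyAnalysisSetError(CompmiError, RuntimeError):
    """An analysis method was handed zero usable rows (e.g. complete-record
    analysis of a dataset with no complete records)."""


class PoolingError(CompmiError, ValueError):
    """Rubin's-rules pooling was requested with fewer than two estimates."""


class ConfigError(CompmiError, ValueError):
    """A configuration document is malformed: unknown keys, type mismatches,
    or mutually exclusive settings."""


class ParseError(CompmiError, ValueError):
    """A tabular input file contains a malformed token; the message reports
    the offending row and column."""
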