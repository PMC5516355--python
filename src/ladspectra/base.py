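"""Shared constants and error types.

The package works on two-class cohorts.  Throughout, the *positive* class is
the rapid kidney-function decliners ("rapid") and the *negative* class the
slow decliners ("slow"); any pair of label strings can be substituted as long
as they are used consistently.
"""

POSITIVE_LABEL = "rapid"
NEGATIVE_LABEL = "slow"

#: Canonical pattern signs and the class each one predicts.
SIGN_POSITIVE = "positive"
SIGN_NEGATIVE = "negative"

SIGN_TO_LABEL = {SIGN_POSITIVE: POSITIVE_LABEL, SIGN_NEGATIVE: NEGATIVE_LABEL}

UNCLASSIFIED = "unclassified"


class LADError(Exception):
    """Base class for all package errors."""


class ConfigError(LADError, ValueError):
    """An invalid configuration value; the message names the field."""


class NormalizationError(LADError):
    """Internal-standard normalization failed for a record."""


class InfeasibleError(LADError):
    """A combinatorial stage has no feasible solution (e.g. an opposite-class
    pair indistinguishable by every binary feature)."""


class GuardError(LADError):
    """An exact/oracle routine was asked to run beyond its enumeration guard."""


class ParseError(LADError):
    """A serialized artifact violates its documented dialect."""
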