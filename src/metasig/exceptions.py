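"""Exception hierarchy.

All package errors derive from :class:`MetasigError` so callers can catch
one base class; most also derive from ``ValueError`` so they behave like
ordinary argument errors in scripting contexts.
"""


class MetasigError(Exception):
    """Base class for all metasig errors."""


class ConfigurationError(MetasigError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class ValidationError(MetasigError, ValueError):
    """Invalid data (negative entries, duplicate identifiers, bad files...)."""


class DegenerateSignatureError(MetasigError, ValueError):
    """A signature column sums to zero and cannot be normalized."""


class DegenerateDendrogramError(MetasigError, ValueError):
    """All pairwise distances are equal; the cophenetic correlation is undefined."""


class DegenerateProfileError(MetasigError, ValueError):
    """A sample has a constant loading profile; correlation distance is undefined."""


class UndefinedDominanceError(MetasigError, ValueError):
    """A sample has all-zero loadings; its dominant signature is undefined."""


class EmptyHitsError(MetasigError, ValueError):
    """No signature metabolite resolves against the pathway universe."""


class PipelineStageError(MetasigError, RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""
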