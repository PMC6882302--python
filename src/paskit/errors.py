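"""Exception hierarchy shared across the package.

All errors derive from :class:`PaskitError` so callers can catch one type;
the subclasses distinguish malformed files, bad parameters, degenerate
inputs and design-table problems, matching the failure modes each stage
documents.
"""


class PaskitError(Exception):
    """Base class for all paskit errors."""


class FormatError(PaskitError, ValueError):
    """A file or token does not conform to the documented dialect."""


class DuplicateKeyError(PaskitError, ValueError):
    """A key that must be unique (pathway, gene, sample) occurs twice."""


class ParameterError(PaskitError, ValueError):
    """A parameter is outside its documented range."""


class DesignError(PaskitError, ValueError):
    """The sample design table is inconsistent with the request."""


class DegenerateInputError(PaskitError, ValueError):
    """Input is structurally valid but degenerate for the operation."""
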