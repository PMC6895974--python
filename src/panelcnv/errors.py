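"""Exception hierarchy for panelcnv.

All package-raised errors derive from :class:`PanelCNVError` so callers
(and the CLI) can distinguish data problems from programming errors.
"""


class PanelCNVError(Exception):
    """Base class for all panelcnv errors."""


class PanelFormatError(PanelCNVError):
    """A panel, depth table, or other input file is malformed."""


class PanelMismatchError(PanelCNVError):
    """Two objects built against different probe panels were combined."""


class EmptyDataError(PanelCNVError):
    """An operation received no usable data (no reads, all-zero depths, ...)."""


class ValidationError(PanelCNVError):
    """An argument violates a documented precondition."""
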