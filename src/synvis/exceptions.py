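"""Exception hierarchy.

All expected failure modes raise a subclass of :class:`SynvisError` so the
command line can turn them into one-line diagnostics instead of tracebacks.
"""


class SynvisError(Exception):
    """Base class for all anticipated errors."""


class InputError(SynvisError):
    """Malformed or inconsistent input file content."""


class ValidationError(SynvisError):
    """Genomes and structural annotations are mutually inconsistent."""


class ZoomError(SynvisError):
    """A region could not be propagated through the syntenic backbone."""


class LayoutError(SynvisError):
    """Invalid combination of layout options."""


class RenderError(SynvisError):
    """Figure could not be produced (unknown format, nothing to draw...)."""
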