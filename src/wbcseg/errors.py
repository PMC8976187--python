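"""Exception hierarchy.

All semantic/parameter problems derive from :class:`ValueError` so callers can
catch broadly; file problems are plain :class:`OSError` raised at the I/O site.
"""


class WBCSegError(Exception):
    """Base class for package-specific errors."""


class FormatError(WBCSegError, ValueError):
    """An input file or array has an unsupported layout (channel count, dtype)."""


class SemanticError(WBCSegError, ValueError):
    """Inputs are individually valid but mutually inconsistent.

    Examples: requesting the H plane of an RGB image, comparing masks of
    different shapes, feeding a GRAY image to an RGB-only step.
    """


class ParameterError(WBCSegError, ValueError):
    """A configuration value is out of its documented range."""


class GenerationError(WBCSegError, RuntimeError):
    """The synthetic-scene generator could not satisfy its constraints."""
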