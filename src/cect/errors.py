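"""Exception hierarchy for the cect package.

All package-raised errors derive from :class:`CectError` so callers can
catch everything from a pipeline stage with one clause.
"""


class CectError(Exception):
    """Base class for all cect errors."""


class ContractError(CectError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(CectError):
    """On-disk volume data is malformed (mixed shapes, mixed bit depths...)."""


class GeometryError(CectError):
    """A VOI or geometric primitive does not fit inside its parent lattice."""


class SegmentationError(CectError):
    """A segmentation step produced an empty or degenerate result."""


class DegenerateWindowError(CectError):
    """A gray-value window or reference pair collapsed to zero width."""
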