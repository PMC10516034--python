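"""Exception hierarchy.

All user-facing failures derive from :class:`TricorrError` so the CLI can map
them onto exit code 2; anything else escaping is a bug.
"""


class TricorrError(Exception):
    """Base class for all tricorr errors."""


class InputError(TricorrError):
    """Invalid user input (bad values, mismatched shapes, unknown labels)."""


class RasterFormatError(InputError):
    """A raster file violates the declared dialect (non-binary, ragged rows)."""


class DegenerateInputError(InputError):
    """Input is structurally valid but the operation is undefined on it
    (e.g. normalizing an all-zero lag tensor from an empty raster)."""


class PlacementError(TricorrError):
    """Motif placement under isolation constraints failed."""
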