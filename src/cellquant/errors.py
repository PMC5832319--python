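"""Exception hierarchy for the cellquant pipeline."""


class CellQuantError(Exception):
    """Base class for all package errors."""


class InputError(CellQuantError):
    """A required input (file, manifest entry) is missing or unreadable."""


class FormatError(CellQuantError):
    """An input file exists but is not a usable raster."""


class ParameterError(CellQuantError):
    """A parameter violates its documented constraints."""


class BoundsError(ParameterError):
    """A region of interest falls outside its target image."""


class GenerationError(CellQuantError):
    """The synthetic-scene generator could not satisfy the requested spec."""


class NoCellsError(CellQuantError):
    """A measurement that requires at least one detected cell found none."""
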