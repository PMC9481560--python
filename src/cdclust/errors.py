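"""Exception hierarchy shared across the package."""


class CDCError(Exception):
    """Base class for all package-specific errors."""


class InputError(CDCError, ValueError):
    """Malformed input data (non-finite values, ragged files, bad labels)."""


class ParameterError(CDCError, ValueError):
    """A parameter outside its admissible range (k, ratio, threshold, n)."""


class DegenerateNeighborhoodError(CDCError, ValueError):
    """A KNN neighborhood whose directions do not span the space.

    Raised by the low-level direction/angle routines; the field-level DCM
    computation catches it and assigns the maximal score instead.
    """


class AllBoundaryError(CDCError, ValueError):
    """Every point was classified as boundary; no cluster seeds remain."""
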