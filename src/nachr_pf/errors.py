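"""Exception hierarchy for nachr_pf."""


class NachrPfError(Exception):
    """Base class for all package-specific errors."""


class PackagedDataError(NachrPfError):
    """Packaged data table failed an integrity check."""


class ResidueError(NachrPfError, ValueError):
    """A character is not a one-letter amino-acid code or the gap character."""


class SegmentError(NachrPfError, ValueError):
    """A subunit segment has the wrong length or is missing."""


class AnchorError(NachrPfError, ValueError):
    """An anchor position leaves part of the -5'..29' window out of bounds."""


class CompositionError(NachrPfError, ValueError):
    """A pentamer composition is malformed or its counts do not sum to five."""


class RegionMissingError(NachrPfError, KeyError):
    """A charge vector lacks a region the caller requires."""


class FitConvergenceError(NachrPfError, RuntimeError):
    """No optimizer start converged."""


class DegenerateDataError(NachrPfError, ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
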