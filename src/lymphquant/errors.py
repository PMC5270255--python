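"""Exception hierarchy. All package errors derive from :class:`LymphquantError`."""


class LymphquantError(Exception):
    """Base class for all lymphquant errors."""


class GeometryError(LymphquantError):
    """A synthetic shape falls outside the canvas or outside the tissue."""


class ConfigurationError(LymphquantError):
    """An invalid or incomplete run/cohort configuration."""


class ShapeError(LymphquantError):
    """Array dimensions of related grids do not match."""


class NoTissueError(LymphquantError):
    """No tissue pixels could be delineated on a section."""


class UndefinedRegionError(LymphquantError):
    """A per-region quantity was requested for an empty reference region."""


class InsufficientDataError(LymphquantError):
    """An estimator was called with no observations."""


class AlignmentError(LymphquantError):
    """A serial section could not be aligned (names the offending section)."""
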