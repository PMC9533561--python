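"""Exception hierarchy shared across the pipeline."""


class SpatialTMEError(Exception):
    """Base class for all package-specific errors."""


class CellTableFormatError(SpatialTMEError):
    """Structural problem in a cell table file (missing column, bad header)."""


class CellTableValidationError(SpatialTMEError):
    """A row or field violates the cell data model (bad value, out of bounds)."""


class NoTumorRegionError(SpatialTMEError):
    """An ROI contains no tumor-compartment cells, so no boundary can be drawn."""


class ConfigurationError(SpatialTMEError):
    """Invalid phenotype definition, unknown marker, or bad config key."""


class UnclassifiableError(SpatialTMEError):
    """A lesion's regional densities do not admit an immunotype call."""


class IntegrityError(SpatialTMEError):
    """Internal inconsistency, e.g. cells counted in a zero-area region."""
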