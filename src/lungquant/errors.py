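"""Exception hierarchy for lungquant."""


class LungQuantError(Exception):
    """Base class for all lungquant errors."""


class ConfigError(LungQuantError):
    """A legend or run configuration is malformed."""


class LegendError(LungQuantError):
    """A class legend is inconsistent or a class name/id is unknown."""


class ShapeError(LungQuantError):
    """Raster dimensions do not match where they must."""


class SegmenterContractError(LungQuantError):
    """A segmenter violated its per-tile output contract."""


class ComparisonError(LungQuantError):
    """Two masks cannot be compared (geometry or legend mismatch)."""


class StratificationError(LungQuantError):
    """No admissible cutoff exists for survival dichotomization."""


class StatisticsError(LungQuantError):
    """A statistical test cannot be computed on the given data."""


class FitError(LungQuantError):
    """A survival regression model failed to fit."""


class SpecError(LungQuantError):
    """A synthetic-data specification is infeasible."""
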