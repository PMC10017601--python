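"""Exception hierarchy shared across the package."""


class FcdScoreError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FcdScoreError, ValueError):
    """An input value violated a documented precondition."""


class MissingConsensusError(FcdScoreError):
    """Observers disagree and no adjudicated value was supplied."""


class DegenerateTableError(FcdScoreError):
    """A contingency table is degenerate for the requested statistic."""


class CapacityError(FcdScoreError):
    """Exact enumeration would exceed the configured table cap."""


class FixtureCorruptionError(FcdScoreError):
    """A packaged fixture failed its checksum or totals check."""


class OrientationError(FcdScoreError):
    """Rate-column orientation search found zero or two feasible solutions."""


class UndefinedMetricError(FcdScoreError):
    """A metric's denominator is zero (e.g. AUC with an empty group)."""
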