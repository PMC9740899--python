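"""Exception taxonomy for the lifting-simulation workflow.

Error classes map one-to-one onto the failure modes of the pipeline:
configuration problems, kinematic infeasibility, recruitment
infeasibility, and incomplete ranking tables.
"""


class LiftsimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LiftsimError):
    """Invalid or inconsistent configuration (bad fractions, unknown names)."""


class InvalidArgumentError(LiftsimError, ValueError):
    """An operation was called with arguments violating its preconditions."""


class InfeasibleTaskError(LiftsimError):
    """Task geometry unreachable for the given anthropometry."""

    def __init__(self, message: str, shortfall_m: float = 0.0):
        super().__init__(message)
        self.shortfall_m = shortfall_m


class DegenerateTraceError(LiftsimError):
    """A signal trace carries no usable extrema (e.g. constant)."""


class NoCycleError(LiftsimError):
    """Fewer than two flat-foot events; no gait cycle can be segmented."""


class KinematicFailureError(LiftsimError):
    """Hard kinematic constraints could not be satisfied (overconstrained)."""

    def __init__(self, message: str, conflicting_drivers=()):
        super().__init__(message)
        self.conflicting_drivers = tuple(conflicting_drivers)


class RecruitmentInfeasibleError(LiftsimError):
    """Equilibrium cannot be satisfied within actuator/contact bounds."""


class IncompleteTableError(LiftsimError):
    """A criteria x alternatives table has missing cells."""

    def __init__(self, message: str, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class MissingDispersionError(LiftsimError):
    """A tie-break policy required dispersions that were not provided."""


class RankDeficiencyError(LiftsimError):
    """Not enough distinct samples for the requested fit."""
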