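"""Exception hierarchy shared across the package."""


class HaplostatError(Exception):
    """Base class for all package-specific errors."""


class InputError(HaplostatError, ValueError):
    """Malformed input file or record (bad characters, empty file, ...)."""


class AlignmentError(HaplostatError, ValueError):
    """Sequences do not form a rectangular alignment."""


class MetadataError(HaplostatError, ValueError):
    """Sample metadata missing, duplicated, or inconsistent with the alignment."""


class SampleSizeError(HaplostatError, ValueError):
    """A statistic was requested for fewer samples than it is defined on."""


class GroupingError(HaplostatError, ValueError):
    """A grouping with too few / empty groups was supplied."""


class UndefinedDistanceError(HaplostatError, ValueError):
    """A pair of sequences shares no unambiguous site, so no distance exists."""


class StatisticUndefinedError(HaplostatError, ValueError):
    """The statistic is undefined on this input (e.g. monomorphic data)."""


class DomainError(HaplostatError, ValueError):
    """A parameter lies outside the mathematical domain of the operation."""


class NumericalError(HaplostatError, ArithmeticError):
    """Numerical evaluation failed to converge or lost its guarantees."""


class FitError(HaplostatError, RuntimeError):
    """Numerical optimisation failed to converge from every starting point."""


class IdentifiabilityError(HaplostatError, ValueError):
    """The data are too degenerate to identify the model parameters."""


class SimulationError(HaplostatError, RuntimeError):
    """A coalescent replicate could not be realised (e.g. infinite-sites overflow)."""
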