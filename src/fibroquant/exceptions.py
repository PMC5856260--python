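"""Exception hierarchy."""


class FibroquantError(Exception):
    """Base class for all package errors."""


class ParameterError(FibroquantError, ValueError):
    """A parameter is out of range, non-finite, or otherwise invalid."""


class BoundsError(FibroquantError, IndexError):
    """Coordinates or a tile fall outside the image."""


class FormatError(FibroquantError, ValueError):
    """A file or in-memory structure does not have the expected layout."""


class ConfigurationError(FibroquantError, ValueError):
    """A model/config does not match the data it is applied to."""


class DegenerateWindowError(FibroquantError, ValueError):
    """Feature window has fewer than two pixels."""


class MissingClassError(FibroquantError, ValueError):
    """A requested class has no pixels/annotations."""

    def __init__(self, classes):
        self.classes = tuple(classes) if not isinstance(classes, str) else (classes,)
        super().__init__(f"missing class(es): {', '.join(self.classes)}")


class ConflictError(FibroquantError, ValueError):
    """Overlapping annotations of different classes."""


class DegenerateTrainingError(FibroquantError, ValueError):
    """Training set has fewer than two classes."""


class StratificationError(FibroquantError, ValueError):
    """A class has fewer samples than the number of CV folds."""


class UndefinedReadoutError(FibroquantError, ZeroDivisionError):
    """A readout denominator is zero (collapsed or empty slide)."""


class AggregationError(FibroquantError, ValueError):
    """Invalid tile aggregation (e.g. duplicate tile ids)."""


class DependencyError(FibroquantError, RuntimeError):
    """A pipeline stage required by a readout has not been run."""
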