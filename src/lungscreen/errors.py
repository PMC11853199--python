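"""Exception hierarchy shared across the pipeline stages."""


class LungscreenError(Exception):
    """Base class for all package errors."""


class ContractError(LungscreenError, ValueError):
    """A precondition on an operation's inputs was violated."""


class FormatError(LungscreenError, ValueError):
    """An input file is unreadable or not in the expected format."""


class EmptyInputError(LungscreenError, ValueError):
    """An input signal or collection is empty where content is required."""


class DegenerateInputError(LungscreenError, ValueError):
    """An input is structurally valid but degenerate (e.g. all-zero signal)."""


class TooShortError(LungscreenError, ValueError):
    """A recording is shorter than one analysis segment."""


class TrainingFailureError(LungscreenError, RuntimeError):
    """Optimization diverged (non-finite loss) during training."""


class UndefinedMetricError(LungscreenError, ZeroDivisionError):
    """A performance metric has a zero denominator; names the class and metric."""

    def __init__(self, metric: str, class_label: str):
        self.metric = metric
        self.class_label = class_label
        super().__init__(
            f"metric '{metric}' undefined for class '{class_label}': zero denominator"
        )
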