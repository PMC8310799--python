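"""Exception hierarchy for milkmr."""


class MilkMRError(Exception):
    """Base class for all milkmr errors."""


class ValidationError(MilkMRError, ValueError):
    """Invalid input values or configuration."""


class DegenerateFitError(MilkMRError):
    """A regression fit is degenerate (perfect fit, separation, rank deficiency)."""


class ConvergenceError(MilkMRError):
    """An iterative fit failed to converge."""


class SchemaError(MilkMRError):
    """A tabular input does not match the documented schema."""
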