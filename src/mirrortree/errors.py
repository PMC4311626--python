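"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: input problems exit 2, degenerate
statistics (zero-variance distance vectors, saturated distances) exit 3.
"""


class MirrortreeError(Exception):
    """Base class for all package-specific errors."""


class InputError(MirrortreeError):
    """Malformed, missing, or inconsistent input data."""


class DegenerateStatisticError(MirrortreeError):
    """A statistic cannot be computed (zero variance, saturated distance)."""
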