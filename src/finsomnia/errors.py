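"""Exception hierarchy.

Three classes mirror the pipeline's exit codes: configuration problems
(bad dialect, malformed config file), data validation problems (a file
that parses but violates an invariant), and runtime pipeline failures.
"""


class FinsomniaError(Exception):
    """Base class for all package errors."""


class ConfigError(FinsomniaError):
    """Invalid configuration: unknown dialect, bad parameter, schema violation.

    May carry a list of individual messages in ``errors`` so that every
    problem in a config file is reported at once.
    """

    def __init__(self, message, errors=None):
        super().__init__(message)
        self.errors = list(errors) if errors is not None else [message]


class ValidationError(FinsomniaError):
    """Input data violates a structural invariant (non-monotonic time,
    too many missing frames, missing gene for a sample, ...)."""


class PipelineError(FinsomniaError):
    """A pipeline stage failed at run time (e.g. every cohort file unreadable)."""
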