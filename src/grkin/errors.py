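"""Exception hierarchy.

Exit-code convention used by the CLI: validation problems (bad input,
schema, out-of-domain arguments) map to 2, numerical failures
(integration breakdown, optimiser failure) map to 3.
"""


class GrkinError(Exception):
    """Base class for all package errors."""


class ValidationError(GrkinError):
    """Invalid user input: unknown model id, schema violation, bad parameter."""


class SchemaError(ValidationError):
    """A delimited data file violates the time-course schema.

    Carries a list of row-level messages with 1-based file line numbers.
    """

    def __init__(self, messages):
        if isinstance(messages, str):
            messages = [messages]
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class SimulationError(GrkinError):
    """ODE integration failed; carries the model id and parameters used."""

    def __init__(self, message, model_id=None, params=None):
        self.model_id = model_id
        self.params = params
        super().__init__(message)


class FitError(GrkinError):
    """Parameter estimation could not produce a solution."""
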