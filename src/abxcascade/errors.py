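"""Exception hierarchy.

Every user-facing failure mode raises a subclass of :class:`AbxCascadeError`
so callers (and the CLI) can distinguish bad inputs from bad configuration
from genuinely degenerate statistical situations.
"""


class AbxCascadeError(Exception):
    """Base class for all package errors."""


class ValidationError(AbxCascadeError):
    """An input record or argument violates the published schema."""


class UnknownAgentError(ValidationError):
    """An antibiotic name is not present in the agent registry."""

    def __init__(self, agent: str):
        self.agent = agent
        super().__init__(f"unknown antibiotic agent: {agent!r}")


class ConfigurationError(AbxCascadeError):
    """The engine / cascade configuration is internally inconsistent."""


class DegenerateFitError(AbxCascadeError):
    """A susceptibility model cannot be fitted (single-class outcome)."""

    def __init__(self, agent: str, message: str):
        self.agent = agent
        super().__init__(f"degenerate fit for agent {agent!r}: {message}")


class UndefinedAdequacyError(AbxCascadeError):
    """Adequacy is undefined: the patient has no clinically relevant isolate."""
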