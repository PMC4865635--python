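"""Exception hierarchy shared by all modules."""


class LeachsimError(Exception):
    """Base class for package errors."""


class ConfigurationError(LeachsimError):
    """A config file is missing a field or refers to unknown entities."""


class ValidationError(LeachsimError, ValueError):
    """A parameter or state value violates a documented invariant."""


class FormatError(LeachsimError):
    """A data file cannot be parsed (bad field, gap in dates, ...)."""


class DomainError(LeachsimError, ValueError):
    """An operation was called outside its mathematical domain."""


class SolverError(LeachsimError):
    """A numerical solver failed to converge within its sub-step budget."""


class ScheduleError(LeachsimError):
    """A management event is inconsistent with the simulation state."""
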