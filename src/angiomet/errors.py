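"""Exception hierarchy shared across the simulator."""


class AngiometError(Exception):
    """Base class for all package errors."""


class ConfigError(AngiometError):
    """Invalid configuration; ``problems`` lists every violation with its key path."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class PreconditionError(AngiometError, ValueError):
    """An operation was called with arguments violating its stated preconditions."""


class StateError(AngiometError):
    """Internal simulation state is inconsistent (e.g. broken occupancy map)."""


class NumericalError(AngiometError):
    """An iterative solve failed to converge; carries the final residual."""

    def __init__(self, message, residual=None):
        self.residual = residual
        if residual is not None:
            message = f"{message} (final residual {residual:.3e})"
        super().__init__(message)


class ValidationError(AngiometError):
    """A data file failed validation; ``problems`` lists every violation."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
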