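"""Exception hierarchy; exit codes used by the command-line interface."""


class MesBalanceError(Exception):
    """Base class for package errors."""

    exit_code = 1


class InputError(MesBalanceError):
    """Invalid or inconsistent user input (bad file, bad value, bad units)."""

    exit_code = 2


class ComputationError(MesBalanceError):
    """A numerical stage failed (e.g. the ODE solver did not converge)."""

    exit_code = 3
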