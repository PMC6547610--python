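"""Exception hierarchy.

Each class maps to a distinct CLI exit code (see :mod:`petpica.cli`).
"""


class PetpicaError(Exception):
    """Base class for all package errors."""

    exit_code = 5


class ConfigError(PetpicaError):
    """Invalid configuration value or inconsistent config combination."""

    exit_code = 2


class IdentifiabilityError(PetpicaError):
    """Simulation geometry cannot support the requested number of
    separable sources (grid too small, blob placement infeasible)."""

    exit_code = 6


class PairingError(PetpicaError):
    """Subjects of the two modalities cannot be paired one-to-one."""

    exit_code = 3


class NumericalError(PetpicaError):
    """Numerical failure: negative eigenvalues, rank deficiency, divergence."""

    exit_code = 4
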