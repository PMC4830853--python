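"""Exception types shared across the package."""


class GmbError(Exception):
    """Base class for all package errors."""


class ConfigError(GmbError):
    """Invalid configuration (bad value, unknown key, missing file)."""


class FormatError(GmbError):
    """Malformed or inconsistent input file."""


class PedigreeError(GmbError):
    """Cyclic or otherwise invalid pedigree."""


class AlignmentError(GmbError):
    """Individual ids do not line up between two inputs."""


class EmptyPanelError(GmbError):
    """Quality control removed every SNP."""


class ConvergenceError(GmbError):
    """Iterative solver failed to converge; carries the convergence log."""

    def __init__(self, message, log=None):
        super().__init__(message)
        self.log = log
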