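"""Exception types shared across the package."""


class AdenosimError(Exception):
    """Base class for package-specific errors."""


class ConfigError(AdenosimError):
    """Invalid configuration, schedule, or argument values."""


class ConvergenceError(AdenosimError):
    """An iterative procedure failed to converge within its budget."""
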