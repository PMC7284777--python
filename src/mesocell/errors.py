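class ParameterError(ValueError):
    """Raised when a physical or algorithmic parameter is out of its valid range."""


class ConfigError(ValueError):
    """Raised when a run configuration is malformed (unknown key, missing input)."""


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge or is unidentifiable."""
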