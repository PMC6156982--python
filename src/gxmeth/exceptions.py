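"""Package-specific exception types."""


class PedigreeError(ValueError):
    """Structural problem in a pedigree (missing parents, cycles, ...)."""


class SingularDesignError(ValueError):
    """Design matrix is rank deficient; carries the offending columns."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"design is rank deficient in columns: {self.columns}")


class ConfigError(ValueError):
    """Invalid run configuration."""
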