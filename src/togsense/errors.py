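"""Exception hierarchy shared by all togsense modules."""


class TogsenseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TogsenseError, ValueError):
    """Invalid simulation or pipeline configuration."""


class GenerationError(TogsenseError, ValueError):
    """Synthetic data could not be generated (e.g. cells outside the volume)."""


class DegenerateInputError(TogsenseError, ValueError):
    """Input carries no usable signal (all-zero or flat volume)."""


class UnknownTastantError(TogsenseError, KeyError):
    """A tastant label is absent from the taste panel."""

    def __init__(self, labels):
        if isinstance(labels, str):
            labels = [labels]
        self.labels = list(labels)
        super().__init__(f"unknown tastant label(s): {', '.join(map(str, self.labels))}")

    def __str__(self):  # KeyError quotes its arg; keep the plain message
        return f"unknown tastant label(s): {', '.join(map(str, self.labels))}"


class SchemaError(TogsenseError, ValueError):
    """A tabular input does not match its declared schema."""


class InsufficientSpotsError(TogsenseError, ValueError):
    """Too few segmented cells to anchor a local coordinate frame."""


class PipelineError(TogsenseError, RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""
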