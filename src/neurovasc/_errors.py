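"""Exception hierarchy shared across the pipeline."""


class NeurovascError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(NeurovascError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(NeurovascError, ValueError):
    """Input is structurally valid but carries no usable signal
    (constant frame, empty parenchyma, zero baseline, ...)."""


class StructuralError(NeurovascError, ValueError):
    """Objects that must agree (shapes, channels, feature configs) do not."""


class ScheduleError(NeurovascError, ValueError):
    """Tracer injection schedule is inconsistent with the hyperstack."""
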