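"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """A parameter or input failed validation; message names the offender."""


class GeometryError(RuntimeError):
    """Degenerate geometry (e.g. collinear landmarks) made an operation impossible."""


class GenerationError(RuntimeError):
    """A sample could not be generated within the configured retry budget."""


class DegenerateInputError(ValueError):
    """Statistical input carries no usable information (e.g. all-tied pairs)."""
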