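"""Exception types shared across the pipeline stages."""


class ParameterError(ValueError):
    """A configuration or generative parameter is invalid (non-finite, out of range)."""


class LengthError(ValueError):
    """A signal or profile has the wrong number of samples for the requested operation."""


class DegenerateInputError(ValueError):
    """Input carries no usable signal (all-zero envelopes, constant profiles)."""


class SchemaError(ValueError):
    """A table or trial set violates the inter-stage file contract."""
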