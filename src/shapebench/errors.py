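"""Exception types shared across the package."""


class ShapeGenerationError(RuntimeError):
    """Rejection sampling exhausted its retry budget for a shape."""


class UndefinedTransferIndexError(ValueError):
    """Transfer index is undefined because the learning HAUC is not positive.

    The transfer index divides by the half-area under the learning curve;
    when a classifier never learns (accuracy at or below chance throughout),
    that denominator is zero or negative and the ratio carries no meaning.
    The condition is surfaced explicitly rather than clipped.
    """
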