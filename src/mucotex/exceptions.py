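"""Error types shared across the pipeline."""


class ValidationError(ValueError):
    """An input violates an operation's preconditions (bad ROI, bad bit depth, ...)."""


class DegenerateDataError(ValueError):
    """The input is formally valid but carries no usable signal (constant image,
    zero-variance feature, empty run-length matrix)."""
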