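"""Exception types shared across the pipeline."""


class DegenerateInputError(ValueError):
    """Raised when an input carries no usable signal for an operation.

    Examples: a constant image offered to Otsu thresholding, a mask whose
    eroded interior is empty, a gray-level co-occurrence matrix with no
    valid pixel pairs. Callers decide whether to skip the sample or abort.
    """
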