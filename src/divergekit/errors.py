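"""Package-wide exception types."""


class DivergekitError(Exception):
    """Base class for divergekit errors."""


class SizingError(DivergekitError):
    """Requested gene complement does not fit in the simulated genome."""


class CoordinateError(DivergekitError):
    """A position or interval falls outside its chromosome."""


class RefMismatchError(DivergekitError):
    """A variant's stated reference base disagrees with the sequence."""
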