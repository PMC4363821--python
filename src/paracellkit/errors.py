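"""Exception hierarchy.

Every error raised on bad scientific input derives from :class:`ParacellError`
so callers (and the CLI) can distinguish validation failures from bugs.
"""


class ParacellError(ValueError):
    """Base class for all domain validation errors."""


class InvalidMeasurementError(ParacellError):
    """A physically impossible electrophysiology record (e.g. raw < blank)."""


class OutOfRangeError(ParacellError):
    """A value outside its physically admissible interval."""


class DegenerateDesignError(ParacellError):
    """A regression / comparison design with no information (e.g. one x value)."""


class NoJunctionError(ParacellError):
    """No junctional signal survived thresholding/skeletonization."""


class UnrelatedSequenceError(ParacellError):
    """An allele sequence that does not align to the reference ORF."""
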