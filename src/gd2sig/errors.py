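"""Exception hierarchy shared across the pipeline."""


class GD2SigError(Exception):
    """Base class for all package errors."""


class InputError(GD2SigError):
    """Malformed or inconsistent user input (CLI exit code 2)."""


class DegenerateDataError(GD2SigError):
    """Data that makes an analysis step undefined, e.g. a single-class cohort
    or a count matrix with no usable reference genes (CLI exit code 3)."""
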