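"""Exception hierarchy shared across the toolkit."""


class CoexkitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(CoexkitError):
    """An input file violates its format contract (duplicates, bad values...)."""


class InputError(CoexkitError):
    """Arguments to an operation violate its preconditions."""


class CoordinateError(CoexkitError):
    """A genomic interval falls outside its chromosome."""


class UnknownIDError(CoexkitError):
    """A requested gene or chromosome identifier is not known."""
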