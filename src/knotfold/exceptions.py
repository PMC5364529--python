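"""Exception hierarchy shared by all fitting modules."""


class KnotfoldError(Exception):
    """Base class for all package errors."""


class DataError(KnotfoldError):
    """Input data violate a type invariant or schema."""


class FitError(KnotfoldError):
    """A fit failed to converge or the data do not support the model."""


class UnidentifiableError(FitError):
    """A parameter cannot be determined from the supplied data.

    The message names the offending parameter or the missing data branch.
    """
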