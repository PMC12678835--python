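"""Exception hierarchy shared by all analysis stages."""


class AfmIndentError(ValueError):
    """Base class for all errors raised by this package."""


class FormatError(AfmIndentError):
    """A file does not conform to the expected on-disk dialect."""


class DataError(AfmIndentError):
    """The data are well-formed but unusable (non-monotone time, short segments, ...)."""


class ContactError(DataError):
    """No contact point could be located on an approach segment."""


class ParameterError(AfmIndentError):
    """A caller-supplied parameter is out of its physical or numerical range."""


class GeometryError(AfmIndentError):
    """An indenter profile is invalid (non-increasing, outside validity range, ...)."""
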