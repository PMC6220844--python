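"""Exception hierarchy shared across the pipeline stages."""


class PmScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PmScreenError, ValueError):
    """A configuration value is out of range, malformed or unknown.

    The message always names the offending field.
    """


class FormatError(PmScreenError, ValueError):
    """An input file or array violates its format contract (e.g. non-increasing m/z)."""


class InputError(PmScreenError, ValueError):
    """An input is structurally valid but unusable (missing controls, empty spot set...)."""


class DegenerateInputError(PmScreenError, ValueError):
    """An input makes the requested computation undefined (zero control mean, all-zero doses)."""
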