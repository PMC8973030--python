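"""Exception hierarchy shared across the package."""


class BindequilError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BindequilError, ValueError):
    """A model parameter violates its validity constraints."""


class NumericalFailureError(BindequilError, RuntimeError):
    """A numerical routine failed to converge within its iteration budget."""


class BracketError(BindequilError, ValueError):
    """A root bracket does not enclose a sign change."""


class UndefinedSpecificityError(BindequilError, ZeroDivisionError):
    """The specificity factor is undefined (no low-affinity complex present)."""


class ConfigurationError(BindequilError, ValueError):
    """An axis/scale/model combination or fit setup is not valid."""


class DataParseError(BindequilError, ValueError):
    """Experimental data text could not be parsed."""
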