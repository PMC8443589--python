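"""Exception hierarchy shared by all mpskit modules."""


class MPSKitError(Exception):
    """Base class for all mpskit errors."""


class ConfigurationError(MPSKitError, ValueError):
    """A generator spec or run configuration violates an invariant.

    The message names the offending field.
    """


class InputError(MPSKitError, ValueError):
    """Runtime input data violates an operation precondition."""
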