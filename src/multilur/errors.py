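"""Exception hierarchy shared across the package."""


class MultiLURError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MultiLURError):
    """A configuration object violates its invariants."""


class DataError(MultiLURError):
    """Input data are structurally invalid or insufficient."""
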