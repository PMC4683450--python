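"""Exception hierarchy shared across the package.

The CLI maps these onto its exit codes: config/parse errors -> 2,
size guard -> 3, convention mismatch -> 4, numerical failure -> 5.
"""


class SlitpermError(Exception):
    """Base class for package errors."""


class ConfigError(SlitpermError):
    """Invalid run configuration, file format, or CLI input."""


class SizeGuardError(SlitpermError):
    """A chain too long for exhaustive enumeration was requested."""


class ConventionMismatchError(SlitpermError):
    """Two density-of-states tables use incompatible counting conventions."""


class WindowError(SlitpermError):
    """A scan window does not bracket the feature being located."""
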