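"""Exception hierarchy shared across the package.

Two failure classes are distinguished so that command-line entry points can
map them to distinct exit codes: invalid *inputs or parameters* (exit 2)
versus *degenerate data* that makes the computation undefined (exit 3).
"""


class NirsrrError(ValueError):
    """Base class for all package-specific errors."""


class ValidationError(NirsrrError):
    """Invalid parameters, malformed files, or violated preconditions."""


class DegenerateInputError(NirsrrError):
    """Structurally valid input on which the computation is undefined
    (e.g. constant signal passed to min-max normalization, fewer than two
    retained troughs for baseline synthesis)."""
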