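"""Exception hierarchy shared across the package.

Validation problems raise :class:`InputError` (or a subclass), configuration
problems :class:`ConfigError`, and malformed on-disk artifacts
:class:`FormatError`.  The CLI maps these onto exit codes 2 (validation) and
3 (I/O).
"""


class ZfscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ZfscreenError):
    """A configuration value is missing, out of range, or inconsistent."""


class InputError(ZfscreenError):
    """An in-memory input violates a precondition."""


class FormatError(ZfscreenError):
    """An on-disk artifact does not parse or fails schema validation."""


class DegenerateNoiseError(InputError):
    """Noise sigma is zero for a non-constant trace; supply a noise floor."""


class UndefinedChangeError(InputError):
    """Percent change is undefined because the baseline velocity is zero."""


class ExcludedWellsError(InputError):
    """Every well of a compound was excluded (e.g. all baselines zero).

    Carries the list of excluded fish ids so callers can log a report.
    """

    def __init__(self, message: str, excluded: list[str]):
        super().__init__(message)
        self.excluded = list(excluded)
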