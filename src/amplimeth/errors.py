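"""Exception hierarchy.

All user-facing failures derive from :class:`AmplimethError` so the CLI can
map them onto exit code 2 (bad input) while genuine bugs surface as exit 1.
"""


class AmplimethError(Exception):
    """Base class for all input/validation failures raised by this package."""


class ConfigError(AmplimethError):
    """Malformed or inconsistent amplicon config / sample manifest."""


class ExtractorFormatError(AmplimethError):
    """A methylation-call file line that cannot be parsed at all."""


class SimSpecError(AmplimethError):
    """Invalid simulation specification; ``field`` names the offender."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"simulation spec field '{field}': {message}")
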