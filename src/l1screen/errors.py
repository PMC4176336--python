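"""Exception hierarchy shared across the screen."""


class L1ScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(L1ScreenError):
    """Unknown species, malformed config, or an impossible class mix."""


class ReferenceIntegrityError(L1ScreenError):
    """A reference model failed its load-time assertions (corrupt reference)."""


class InputError(L1ScreenError):
    """Invalid user input: bad alphabet, empty sequence, out-of-range coordinate."""


class MutationSpecError(L1ScreenError):
    """A mutation specification is inconsistent with the reference model."""
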