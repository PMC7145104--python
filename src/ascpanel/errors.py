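"""Exception hierarchy shared by all pipeline stages."""


class AscPanelError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(AscPanelError):
    """Malformed input file (ragged PED row, duplicate locus id, ...)."""


class ConfigError(AscPanelError):
    """Invalid parameter or configuration value."""


class EmptyPanelError(AscPanelError):
    """A filtering stage removed every locus."""
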