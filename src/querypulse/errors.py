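"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


class UrlParseError(ValueError):
    """A clicked URL does not yield a registrable domain."""
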