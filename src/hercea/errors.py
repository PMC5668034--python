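"""Exception types shared across the package."""


class ConfigurationError(Exception):
    """A scenario configuration is incomplete or internally inconsistent."""


class NumericalError(Exception):
    """The cohort simulation produced an invalid intermediate quantity."""
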