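"""Exception hierarchy mapped onto CLI exit codes."""


class MitoscreenError(Exception):
    """Base class for all fatal pipeline errors."""

    exit_code = 1


class ConfigError(MitoscreenError):
    """Invalid configuration (bad theta, negative radius, malformed weights...)."""

    exit_code = 2


class InputError(MitoscreenError):
    """Unreadable, empty or malformed input data."""

    exit_code = 3


class EmptyResultError(MitoscreenError):
    """A stage produced an empty result that later stages cannot work with
    (empty corpus after filtering, empty embedding vocabulary, ...)."""

    exit_code = 4
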