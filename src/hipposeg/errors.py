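"""Exception hierarchy shared across the package."""


class HipposegError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(HipposegError, ValueError):
    """A parameter or input violates a documented precondition."""


class InvalidDatasetError(HipposegError, ValueError):
    """A dataset violates a structural requirement (e.g. no minority class)."""


class FormatError(HipposegError, ValueError):
    """A file could not be parsed as the expected format."""
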