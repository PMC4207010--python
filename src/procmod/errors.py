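"""Exception types shared across the package."""


class ProcmodError(Exception):
    """Base class for all package errors."""


class ParseError(ProcmodError):
    """A file could not be parsed under the declared dialect."""


class ContractError(ProcmodError):
    """A caller violated an operation precondition."""
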