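"""Exception types shared across the package."""


class PilafError(Exception):
    """Base class for all package errors."""


class RegionParseError(PilafError, ValueError):
    """A region string could not be parsed into a genomic interval."""


class ContractError(PilafError, ValueError):
    """A caller violated a documented precondition."""


class ValidationError(PilafError, ValueError):
    """Input data violated a structural invariant (e.g. overlapping
    alignment segments, negative counts)."""
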