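"""Exception types shared across vdjflow modules."""


class VdjflowError(Exception):
    """Base class for all vdjflow errors."""


class SchemaError(VdjflowError):
    """A table is missing a mandatory column or contains invalid values."""


class IntegrityError(VdjflowError):
    """Identifiers clash or tables that must align do not."""


class ParameterError(VdjflowError):
    """A caller-supplied parameter is out of range or unknown."""
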