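"""Exception hierarchy for asokd."""


class AsokdError(Exception):
    """Base class for all asokd errors."""


class FormatError(AsokdError):
    """A file does not conform to its declared on-disk format."""


class SchemaError(AsokdError):
    """A table is missing required columns or contains invalid values."""


class DataIntegrityError(AsokdError):
    """Counts and metadata disagree (e.g. mismatched barcodes)."""
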