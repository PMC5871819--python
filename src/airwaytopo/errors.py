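"""Exception types shared across the package."""


class TreeParseError(ValueError):
    """A tree file could not be parsed (message names the offending line)."""


class TreeStructureError(ValueError):
    """Parsed records do not form a valid rooted forest."""


class DegenerateInputError(ValueError):
    """Input has no usable geometric content (e.g. all points coincide)."""


class MissingLabelsError(ValueError):
    """An operation requires labels (generations, height) that are absent."""


class UnitMismatchError(ValueError):
    """Two barcodes with different degrees or scale units were compared."""
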