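"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file or table violates the expected structure (missing column, bad code)."""


class ParseError(ValueError):
    """A row holds a value that cannot be interpreted; message cites the row."""
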