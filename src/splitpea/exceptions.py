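"""Exception hierarchy."""


class SplitpeaError(Exception):
    """Base class for all splitpea errors."""


class InputFormatError(SplitpeaError):
    """An input file does not conform to its documented format."""
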