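"""Exception hierarchy shared across the package."""


class SynmotifError(Exception):
    """Base class for all package errors."""


class FrameError(SynmotifError, ValueError):
    """A nucleotide sequence is not a valid in-frame CDS."""


class MotifSpecError(SynmotifError, ValueError):
    """A motif specification is malformed (alphabet, lengths, emptiness)."""


class EstimationError(SynmotifError, ValueError):
    """A null model cannot be estimated or evaluated from the given data."""


class EnumerationGuardError(SynmotifError, ValueError):
    """A brute-force enumeration would exceed the configured size guard."""


class AdmissionError(SynmotifError, ValueError):
    """No admissible sequences survived input validation."""
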