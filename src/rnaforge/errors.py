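"""Exception types shared across the toolkit."""


class RnaforgeError(Exception):
    """Base class for toolkit errors."""


class DegenerateInputError(RnaforgeError, ValueError):
    """Raised for geometrically degenerate inputs (singular matrices,
    collinear atom triples, reflection-dominant orientations)."""


class IngestError(RnaforgeError, ValueError):
    """Raised when external data (sequences, structures, pools) fails
    validation on ingest."""
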