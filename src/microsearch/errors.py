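"""Exception hierarchy shared across modules."""


class MicrosearchError(Exception):
    """Base class for all package errors."""


class NewickParseError(MicrosearchError):
    """Malformed newick input (position reported where determinable)."""


class ProfileFormatError(MicrosearchError):
    """Malformed OTU-table input (negative counts, duplicate rows, bad JSON)."""


class ProfileValueError(MicrosearchError):
    """Invalid profile for the requested operation (empty, non-integer, ...)."""


class UnknownLeafError(MicrosearchError):
    """Profile references OTU labels that are not leaves of the phylogeny."""

    def __init__(self, labels):
        self.labels = sorted(labels)
        super().__init__(f"OTU labels not found in the tree: {self.labels}")


class NotNormalizedError(MicrosearchError):
    """Abundance vector does not sum to 1 within tolerance."""


class NonMetricError(MicrosearchError):
    """Distance function violated a metric axiom during index construction."""


class MissingDistanceError(MicrosearchError):
    """A required pre-computed distance cell is absent."""


class EmptyContextError(MicrosearchError):
    """No database sample was evaluated against every query sample."""
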