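"""Exception hierarchy."""


class AnchorNetError(Exception):
    """Base class for all package errors."""


class NetworkFormatError(AnchorNetError):
    """A network, node-list or pathway file violates the expected format."""


class OntologyError(AnchorNetError):
    """Unknown term or malformed detection-method ontology."""


class PathwayError(AnchorNetError):
    """A pathway graph is unusable (empty group, no anchors/terminals, ...)."""


class QueryError(AnchorNetError):
    """An anchored-reconstruction query is invalid or infeasible."""


class ModelError(AnchorNetError):
    """A trained model is missing, incompatible or was fed bad data."""
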