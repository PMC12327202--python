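"""Exception hierarchy shared across the package."""


class GRNPetriError(Exception):
    """Base class for all package errors."""


class ValidationError(GRNPetriError):
    """A network violates a structural invariant."""


class UnknownReferenceError(GRNPetriError):
    """An operation referenced a node, place, or transition that does not exist."""


class GraphMLError(GRNPetriError):
    """GraphML input is malformed or lacks a mandatory attribute key."""


class TransformError(GRNPetriError):
    """A transformation rule could not be applied."""


class PerturbationError(GRNPetriError):
    """A perturbation targeted an element of the wrong kind."""


class PairingError(GRNPetriError):
    """Two genes were paired for evaluation without a shared targeting miRNA."""
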