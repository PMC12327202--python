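"""In silico perturbations: miRNA knockout and concentration changes."""

from __future__ import annotations

from . import grn as g
from .errors import PerturbationError, UnknownReferenceError
from .petrinet import ENTITY, GENERATION, PetriNet


def _find_mirna_place(net: PetriNet, mirna: str):
    """Resolve a miRNA by place id or by originating GRN node id."""
    if mirna in net.places:
        place = net.places[mirna]
    else:
        candidates = [
            pid
            for pid, origin in net.provenance.items()
            if origin == mirna and pid in net.places
        ]
        if not candidates:
            raise UnknownReferenceError(f"no place corresponds to {mirna!r}")
        place = net.places[candidates[0]]
    if place.role != ENTITY or place.entity_type != g.MIRNA:
        raise PerturbationError(f"{mirna!r} is not a miRNA pool place")
    return place


def knockout_mirna(net: PetriNet, mirna: str) -> PetriNet:
    """Return a copy of the net with a miRNA's expression knocked out.

    The miRNA's generation transition is deactivated and the pool's start
    tokens are zeroed, so no residual start tokens bind in cycle 0.  The
    inhibitor arcs and decay transitions stay in place; they simply never
    see tokens.
    """
    out = net.copy()
    place = _find_mirna_place(out, mirna)
    feeders = [
        t
        for t in out.transitions.values()
        if t.role == GENERATION
        and any(a.source == t.id and a.target == place.id for a in out.arcs)
    ]
    if not feeders:
        raise PerturbationError(f"miRNA pool {place.id!r} has no generation transition")
    for t in feeders:
        t.active = False
    place.start_tokens = 0
    return out


def set_concentration(network: g.GRN, node_id: str, value: float) -> g.GRN:
    """Return a copy of the GRN with a gene's or miRNA's concentration changed.

    Setting a miRNA to 0 is equivalent, after transformation, to a
    knockout of that miRNA on the transformed net.  Concentrations are
    gene/miRNA-level; targeting an mRNA node is an error.
    """
    if value < 0:
        raise PerturbationError("concentration must be >= 0")
    out = network.copy()
    node = out.node(node_id)
    if node.label not in (g.DNA, g.MIRNA):
        raise PerturbationError(
            f"concentration can only be set on DNA or miRNA nodes, {node_id!r} is {node.label}"
        )
    node.start_concentration = float(value)
    return out
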