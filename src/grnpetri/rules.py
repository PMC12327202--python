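"""Rule-based transformation of a GRN into a functional Petri net.

Four rules turn the biological network into an executable model:

1. Each gene (DNA node) becomes a pool place fed by a generation
   transition; arc weight and start tokens equal the gene's start
   concentration (rounded up).
2. Each miRNA node becomes a pool place fed the same way.
3. Each miRNA -> isoform targeting edge becomes an inhibitor arc onto the
   isoform's process transition, and each distinct (miRNA, gene) pair gets
   a decay transition that binds and removes min(miRNA pool, DNA pool)
   tokens from both pools into a counter place.  Decay fires before the
   process (delay 0.1 vs 0.7), so available miRNA binds DNA first and only
   leftover miRNA keeps the process inhibited.
4. Each isoform's process transition drains the gene pool into a result
   place named GENE_TRANSCRIPT_FINAL; both arc weights track the current
   DNA-pool marking.

Element ids are derived deterministically from GRN ids, so the same GRN
always yields an identical net.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import grn as g
from .errors import TransformError
from .petrinet import (
    COUNTER,
    DECAY,
    ENTITY,
    GENERATION,
    INHIBITOR,
    PROCESS,
    RESULT,
    Arc,
    Constant,
    MarkingOf,
    MinOf,
    PetriNet,
    Place,
    Transition,
    validate_net,
)


@dataclass
class RuleApplication:
    """One rule firing: which GRN elements it consumed, which net elements it produced."""

    rule: int
    grn_elements: list[str]
    pn_elements: list[str]


RuleApplicationLog = list


# deterministic id scheme
def dna_place_id(gene: str) -> str:
    return f"P_DNA_{gene}"


def mirna_place_id(mirna: str) -> str:
    return f"P_MIR_{mirna}"


def generation_id(node: str) -> str:
    return f"T_GEN_{node}"


def process_id(transcript: str) -> str:
    return f"T_MRNA_{transcript}"


def decay_id(mirna: str, gene: str) -> str:
    return f"T_DECAY_{mirna}_{gene}"


def counter_id(mirna: str, gene: str) -> str:
    return f"P_CNT_{mirna}_{gene}"


def result_place_name(gene: str, transcript: str) -> str:
    return f"{gene}_{transcript}_FINAL"


def result_place_id(gene: str, transcript: str) -> str:
    return f"P_{result_place_name(gene, transcript)}"


def _generation_rule(node: g.GRNNode, entity_type: str) -> tuple[Place, Transition, Arc]:
    if node.start_concentration is None or node.start_concentration < 0:
        raise TransformError(
            f"{entity_type} node {node.id!r} needs a start concentration >= 0"
        )
    rate = math.ceil(node.start_concentration)
    pid = dna_place_id(node.id) if entity_type == g.DNA else mirna_place_id(node.id)
    place = Place(
        id=pid,
        name=node.name,
        start_tokens=rate,
        role=ENTITY,
        color=node.color,
        entity_type=entity_type,
    )
    # concentration 0 means no expression: the feeding transition is created
    # but deactivated, matching an in silico knockout of the node
    trans = Transition(id=generation_id(node.id), role=GENERATION, active=rate > 0)
    arc = Arc(source=trans.id, target=place.id, weight=Constant(max(rate, 1)))
    return place, trans, arc


def rule1_dna(node: g.GRNNode) -> tuple[Place, Transition, Arc]:
    """Gene pool place + constant-rate generation transition."""
    if node.label != g.DNA:
        raise TransformError(f"rule 1 applies to DNA nodes, got {node.label}")
    return _generation_rule(node, g.DNA)


def rule2_mirna(node: g.GRNNode) -> tuple[Place, Transition, Arc]:
    """miRNA pool place + constant-rate generation transition."""
    if node.label != g.MIRNA:
        raise TransformError(f"rule 2 applies to miRNA nodes, got {node.label}")
    return _generation_rule(node, g.MIRNA)


def rule3_inhibition(
    mirna_place: Place, dna_place: Place, mrna_node: g.GRNNode
) -> tuple[Transition, Arc, Transition, Place, list[Arc]]:
    """Inhibition of one isoform by one miRNA, plus the binding/decay path.

    Returns the isoform's process transition, the inhibitor arc, the decay
    transition for the (miRNA, gene) pair, its counter place, and the three
    min-weighted decay arcs.  The caller deduplicates: one process
    transition per isoform, one decay/counter per (miRNA, gene) pair.
    """
    mirna = mirna_place.name
    gene = dna_place.name
    process = Transition(id=process_id(mrna_node.id), role=PROCESS, color=mrna_node.color)
    inhibitor = Arc(
        source=mirna_place.id, target=process.id, kind=INHIBITOR, weight=Constant(1)
    )
    decay = Transition(id=decay_id(mirna, gene), role=DECAY)
    counter = Place(id=counter_id(mirna, gene), name=counter_id(mirna, gene), role=COUNTER)
    bound = MinOf(mirna_place.id, dna_place.id)
    decay_arcs = [
        Arc(source=mirna_place.id, target=decay.id, weight=bound),
        Arc(source=dna_place.id, target=decay.id, weight=bound),
        Arc(source=decay.id, target=counter.id, weight=bound),
    ]
    return process, inhibitor, decay, counter, decay_arcs


def rule4_production(
    dna_place: Place, process: Transition, gene: str, transcript: str
) -> tuple[list[Arc], Place]:
    """Production path: gene pool -> process transition -> result place."""
    result = Place(
        id=result_place_id(gene, transcript),
        name=result_place_name(gene, transcript),
        role=RESULT,
    )
    arcs = [
        Arc(source=dna_place.id, target=process.id, weight=MarkingOf(dna_place.id)),
        Arc(source=process.id, target=result.id, weight=MarkingOf(dna_place.id)),
    ]
    return arcs, result


def transform(network: g.GRN) -> tuple[PetriNet, list[RuleApplication]]:
    """Apply rules 1-4 to a validated GRN; returns the net and the rule log."""
    network.require_valid()
    net = PetriNet()
    log: list[RuleApplication] = []

    def add_place(place: Place, origin: str | None = None):
        if place.id in net.places:
            raise TransformError(f"duplicate place id {place.id!r}")
        net.places[place.id] = place
        if origin is not None:
            net.provenance[place.id] = origin

    def add_transition(trans: Transition, origin: str | None = None):
        if trans.id in net.transitions:
            raise TransformError(f"duplicate transition id {trans.id!r}")
        net.transitions[trans.id] = trans
        if origin is not None:
            net.provenance[trans.id] = origin

    # rules 1 and 2: entity pools
    for node in sorted(network.genes(), key=lambda n: n.id):
        place, trans, arc = rule1_dna(node)
        add_place(place, node.id)
        add_transition(trans, node.id)
        net.arcs.append(arc)
        log.append(RuleApplication(1, [node.id], [place.id, trans.id]))
    for node in sorted(network.mirnas(), key=lambda n: n.id):
        place, trans, arc = rule2_mirna(node)
        add_place(place, node.id)
        add_transition(trans, node.id)
        net.arcs.append(arc)
        log.append(RuleApplication(2, [node.id], [place.id, trans.id]))

    # process transitions exist for every isoform, targeted or not
    parent: dict[str, str] = {}
    for mrna in sorted(network.transcripts(), key=lambda n: n.id):
        parent[mrna.id] = network.parent_of(mrna.id)
        add_transition(
            Transition(id=process_id(mrna.id), role=PROCESS, color=mrna.color), mrna.id
        )

    # rule 3: inhibitor arcs per targeting edge, decay per (miRNA, gene) pair
    seen_pairs: set[tuple[str, str]] = set()
    for mirna in sorted(network.mirnas(), key=lambda n: n.id):
        mir_place = net.places[mirna_place_id(mirna.id)]
        for transcript_id in network.targets_of(mirna.id):
            gene = parent[transcript_id]
            dna_place = net.places[dna_place_id(gene)]
            mrna_node = network.nodes[transcript_id]
            process, inhibitor, decay, counter, decay_arcs = rule3_inhibition(
                mir_place, dna_place, mrna_node
            )
            net.arcs.append(inhibitor)
            produced = [process.id, f"{inhibitor.source}->{inhibitor.target}"]
            if (mirna.id, gene) not in seen_pairs:
                seen_pairs.add((mirna.id, gene))
                add_transition(decay)
                add_place(counter)
                net.arcs.extend(decay_arcs)
                produced += [decay.id, counter.id]
            log.append(
                RuleApplication(3, [mirna.id, transcript_id, gene], produced)
            )

    # rule 4: production into result places
    for mrna in sorted(network.transcripts(), key=lambda n: n.id):
        gene = parent[mrna.id]
        dna_place = net.places[dna_place_id(gene)]
        process = net.transitions[process_id(mrna.id)]
        arcs, result = rule4_production(dna_place, process, gene, mrna.id)
        add_place(result, mrna.id)
        net.arcs.extend(arcs)
        log.append(RuleApplication(4, [mrna.id, gene], [result.id]))

    problems = validate_net(net)
    if problems:  # transformation of a valid GRN must produce a valid net
        raise TransformError("transformed net is invalid: " + "; ".join(problems))
    return net, log


def write_rule_log(log: list[RuleApplication], path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rule", "grn_elements", "pn_elements"])
        for entry in log:
            writer.writerow(
                [entry.rule, ";".join(entry.grn_elements), ";".join(entry.pn_elements)]
            )
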