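"""Functional Petri net with inhibitor arcs.

Places hold non-negative integer token counts; transitions fire after a
fixed delay; arc weights may be functions of the current marking
("functional" arcs), re-evaluated at every enabling check and firing.  An
inhibitor arc disables its transition while the source place's marking is
at or above the arc weight (weight 1: the place must be empty) and never
consumes tokens.

Sanitization: every weight evaluates to an integer by rounding up
(``ceil``), and weights on arcs *into* a transition are additionally
clamped to ``max(f, 1)`` so a transition can never be enabled by an empty
pre-place.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Union

from .errors import UnknownReferenceError, ValidationError

# place roles
ENTITY = "entity"
COUNTER = "counter"
RESULT = "result"

# transition roles and their default delays
GENERATION = "generation"
PROCESS = "process"
DECAY = "decay"
DEFAULT_DELAYS = {GENERATION: 1.0, PROCESS: 0.7, DECAY: 0.1}

REGULAR = "regular"
INHIBITOR = "inhibitor"

#: A marking assigns a non-negative integer token count to every place.
Marking = dict[str, int]


# ---------------------------------------------------------------------------
# weight expressions


@dataclass(frozen=True)
class Constant:
    value: float


@dataclass(frozen=True)
class MarkingOf:
    place: str


@dataclass(frozen=True)
class MinOf:
    place_a: str
    place_b: str


WeightExpr = Union[Constant, MarkingOf, MinOf]


def _raw_value(expr: WeightExpr, marking: Marking) -> float:
    if isinstance(expr, Constant):
        return expr.value
    if isinstance(expr, MarkingOf):
        if expr.place not in marking:
            raise UnknownReferenceError(f"weight references unknown place {expr.place!r}")
        return marking[expr.place]
    if isinstance(expr, MinOf):
        for pid in (expr.place_a, expr.place_b):
            if pid not in marking:
                raise UnknownReferenceError(f"weight references unknown place {pid!r}")
        return min(marking[expr.place_a], marking[expr.place_b])
    raise TypeError(f"not a weight expression: {expr!r}")


def evaluate_weight(expr: WeightExpr, marking: Marking, into_transition: bool = False) -> int:
    """Evaluate a functional arc weight against the current marking.

    The raw value is rounded up to an integer; for arcs into a transition
    the result is clamped to at least 1, so that e.g. a decay transition
    whose miRNA pool is empty stays disabled rather than firing for free.
    """
    value = math.ceil(_raw_value(expr, marking))
    if into_transition:
        value = max(value, 1)
    return value


def _weight_to_json(expr: WeightExpr) -> dict:
    if isinstance(expr, Constant):
        return {"constant": expr.value}
    if isinstance(expr, MarkingOf):
        return {"marking_of": expr.place}
    if isinstance(expr, MinOf):
        return {"min_of": [expr.place_a, expr.place_b]}
    raise TypeError(f"not a weight expression: {expr!r}")


def _weight_from_json(data: dict) -> WeightExpr:
    if "constant" in data:
        return Constant(data["constant"])
    if "marking_of" in data:
        return MarkingOf(data["marking_of"])
    if "min_of" in data:
        a, b = data["min_of"]
        return MinOf(a, b)
    raise ValueError(f"unknown weight expression encoding: {data!r}")


# ---------------------------------------------------------------------------
# net elements


@dataclass
class Place:
    id: str
    name: str
    start_tokens: int = 0
    role: str = ENTITY
    color: str = ""
    #: for entity places, which pool this is ("DNA" or "miRNA")
    entity_type: str | None = None


@dataclass
class Transition:
    id: str
    role: str
    delay: float | None = None
    active: bool = True
    color: str = ""

    def __post_init__(self):
        if self.delay is None:
            self.delay = DEFAULT_DELAYS.get(self.role, 1.0)


@dataclass
class Arc:
    source: str
    target: str
    kind: str = REGULAR
    weight: WeightExpr = Constant(1)


@dataclass
class PetriNet:
    places: dict[str, Place] = field(default_factory=dict)
    transitions: dict[str, Transition] = field(default_factory=dict)
    arcs: list[Arc] = field(default_factory=list)
    #: Petri net element id -> originating GRN node id
    provenance: dict[str, str] = field(default_factory=dict)

    # -- topology helpers --------------------------------------------------

    def input_arcs(self, transition_id: str) -> list[Arc]:
        return [a for a in self.arcs if a.target == transition_id]

    def output_arcs(self, transition_id: str) -> list[Arc]:
        return [a for a in self.arcs if a.source == transition_id]

    def initial_marking(self) -> Marking:
        return {pid: p.start_tokens for pid, p in self.places.items()}

    def result_places(self) -> list[Place]:
        return sorted((p for p in self.places.values() if p.role == RESULT), key=lambda p: p.id)

    def counter_places(self) -> list[Place]:
        return sorted((p for p in self.places.values() if p.role == COUNTER), key=lambda p: p.id)

    def copy(self) -> "PetriNet":
        return PetriNet(
            places={pid: replace(p) for pid, p in self.places.items()},
            transitions={tid: replace(t) for tid, t in self.transitions.items()},
            arcs=[replace(a) for a in self.arcs],
            provenance=dict(self.provenance),
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "places": [
                {
                    "id": p.id,
                    "name": p.name,
                    "start_tokens": p.start_tokens,
                    "role": p.role,
                    "color": p.color,
                    "entity_type": p.entity_type,
                }
                for p in self.places.values()
            ],
            "transitions": [
                {
                    "id": t.id,
                    "role": t.role,
                    "delay": t.delay,
                    "active": t.active,
                    "color": t.color,
                }
                for t in self.transitions.values()
            ],
            "arcs": [
                {
                    "source": a.source,
                    "target": a.target,
                    "kind": a.kind,
                    "weight": _weight_to_json(a.weight),
                }
                for a in self.arcs
            ],
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PetriNet":
        net = cls()
        for p in data.get("places", []):
            net.places[p["id"]] = Place(
                id=p["id"],
                name=p.get("name", p["id"]),
                start_tokens=int(p.get("start_tokens", 0)),
                role=p.get("role", ENTITY),
                color=p.get("color", ""),
                entity_type=p.get("entity_type"),
            )
        for t in data.get("transitions", []):
            net.transitions[t["id"]] = Transition(
                id=t["id"],
                role=t["role"],
                delay=t.get("delay"),
                active=bool(t.get("active", True)),
                color=t.get("color", ""),
            )
        for a in data.get("arcs", []):
            net.arcs.append(
                Arc(
                    source=a["source"],
                    target=a["target"],
                    kind=a.get("kind", REGULAR),
                    weight=_weight_from_json(a["weight"]),
                )
            )
        net.provenance = dict(data.get("provenance", {}))
        return net

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def read_json(cls, path) -> "PetriNet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# validation


def _weight_places(expr: WeightExpr) -> list[str]:
    if isinstance(expr, MarkingOf):
        return [expr.place]
    if isinstance(expr, MinOf):
        return [expr.place_a, expr.place_b]
    return []


def validate_net(net: PetriNet) -> list[str]:
    """Report every structural violation; an empty list means the net is valid.

    Checks bipartiteness, dangling endpoints, inhibitor-arc direction and
    weight, weight-expression references, non-negative start tokens,
    positive delays, and result-place naming.
    """
    problems: list[str] = []
    for place in net.places.values():
        if place.start_tokens < 0:
            problems.append(f"place {place.id!r}: negative start tokens")
        if place.role == RESULT and not place.name.endswith("_FINAL"):
            problems.append(f"result place {place.id!r} is not named GENE_TRANSCRIPT_FINAL style")
        if place.role not in (ENTITY, COUNTER, RESULT):
            problems.append(f"place {place.id!r}: unknown role {place.role!r}")
    for trans in net.transitions.values():
        if trans.delay is None or trans.delay <= 0:
            problems.append(f"transition {trans.id!r}: delay must be > 0")
        if trans.role not in (GENERATION, PROCESS, DECAY):
            problems.append(f"transition {trans.id!r}: unknown role {trans.role!r}")
    for arc in net.arcs:
        src_place = arc.source in net.places
        src_trans = arc.source in net.transitions
        tgt_place = arc.target in net.places
        tgt_trans = arc.target in net.transitions
        if not (src_place or src_trans):
            problems.append(f"arc {arc.source!r}->{arc.target!r}: unknown source")
            continue
        if not (tgt_place or tgt_trans):
            problems.append(f"arc {arc.source!r}->{arc.target!r}: unknown target")
            continue
        if src_place == tgt_place:
            problems.append(
                f"arc {arc.source!r}->{arc.target!r} violates bipartiteness "
                "(must connect a place and a transition)"
            )
            continue
        if arc.kind == INHIBITOR:
            if not (src_place and tgt_trans):
                problems.append(
                    f"inhibitor arc {arc.source!r}->{arc.target!r} must run place -> transition"
                )
            if not (isinstance(arc.weight, Constant) and arc.weight.value == 1):
                problems.append(
                    f"inhibitor arc {arc.source!r}->{arc.target!r} must have constant weight 1"
                )
        elif arc.kind != REGULAR:
            problems.append(f"arc {arc.source!r}->{arc.target!r}: unknown kind {arc.kind!r}")
        for pid in _weight_places(arc.weight):
            if pid not in net.places:
                problems.append(
                    f"arc {arc.source!r}->{arc.target!r}: weight references unknown place {pid!r}"
                )
    return problems


def require_valid(net: PetriNet) -> PetriNet:
    problems = validate_net(net)
    if problems:
        raise ValidationError("; ".join(problems))
    return net
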