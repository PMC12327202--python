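"""Delay-ordered discrete simulation of the transformed Petri nets.

Each time unit is one cycle with a fixed firing schedule derived from the
transition delays: decay transitions fire at k+0.1, process (mRNA)
transitions at k+0.7, and generation transitions at k+1.  Cycle 0 runs on
the start tokens.  Within a phase, transitions fire at most once each in a
deterministic conflict order (sorted id unless a priority list is given),
and enablement is re-checked before every firing because functional arc
weights depend on the marking.

Biologically: every cycle, the minimum of available miRNA and DNA binds
and decays first (logged in a counter place), then each isoform whose
miRNA pools are all empty processes the remaining DNA into its result
place, and finally the constant-rate generation refills the pools.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ValidationError
from .petrinet import (
    DECAY,
    GENERATION,
    INHIBITOR,
    PROCESS,
    REGULAR,
    Marking,
    PetriNet,
    Transition,
    evaluate_weight,
    validate_net,
)


@dataclass
class SimulationConfig:
    """Schedule and conflict-resolution settings.

    ``horizon`` is in time units; offsets locate the firing phases inside a
    unit cycle and must satisfy 0 < decay_offset < process_offset <
    generation_period.  ``priority`` optionally lists transition ids that
    fire first within their phase (remaining ties break on sorted id).
    """

    horizon: int = 20
    decay_offset: float = 0.1
    process_offset: float = 0.7
    generation_period: float = 1.0
    priority: Sequence[str] | None = None

    def __post_init__(self):
        if not (0 < self.decay_offset < self.process_offset < self.generation_period):
            raise ValidationError(
                "offsets must satisfy 0 < decay < process < generation period"
            )
        if self.horizon < 0:
            raise ValidationError("horizon must be >= 0")

    def order(self, ids) -> list[str]:
        if self.priority is None:
            return sorted(ids)
        rank = {tid: i for i, tid in enumerate(self.priority)}
        return sorted(ids, key=lambda tid: (rank.get(tid, len(rank)), tid))


@dataclass
class SimulationResult:
    """Trajectory snapshots at integer times plus final totals.

    ``finals`` maps result-place names (GENE_TRANSCRIPT_FINAL) to their
    token totals at the horizon; ``bound`` does the same for the counter
    places that accumulate miRNA-bound-and-decayed DNA.
    """

    times: list[int]
    trajectory: list[Marking]
    finals: dict[str, int]
    bound: dict[str, int]
    place_names: dict[str, str] = field(default_factory=dict)
    place_roles: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# firing semantics


def is_enabled(net: PetriNet, transition: Transition | str, marking: Marking) -> bool:
    """A transition is enabled iff it is active, every regular input place
    holds at least the (sanitized) arc weight, and every inhibiting place
    holds strictly fewer tokens than the inhibitor weight."""
    t = net.transitions[transition] if isinstance(transition, str) else transition
    if not t.active:
        return False
    for arc in net.input_arcs(t.id):
        weight = evaluate_weight(arc.weight, marking, into_transition=True)
        tokens = marking[arc.source]
        if arc.kind == INHIBITOR:
            if tokens >= weight:
                return False
        else:
            if tokens < weight:
                return False
    return True


def fire(net: PetriNet, transition: Transition | str, marking: Marking) -> Marking:
    """Fire an enabled transition; returns the successor marking.

    All arc weights are evaluated once against the pre-firing marking and
    applied atomically, so e.g. a decay removes the same min(miRNA, DNA)
    amount from both pools that it adds to its counter.
    """
    t = net.transitions[transition] if isinstance(transition, str) else transition
    if not is_enabled(net, t, marking):
        raise ValidationError(f"transition {t.id!r} fired while disabled")
    removals = [
        (arc.source, evaluate_weight(arc.weight, marking, into_transition=True))
        for arc in net.input_arcs(t.id)
        if arc.kind == REGULAR
    ]
    additions = [
        (arc.target, evaluate_weight(arc.weight, marking, into_transition=False))
        for arc in net.output_arcs(t.id)
    ]
    out = dict(marking)
    for pid, w in removals:
        out[pid] -= w
        if out[pid] < 0:
            raise ValidationError(f"marking of {pid!r} went negative")
    for pid, w in additions:
        out[pid] += w
    return out


def _phase(net: PetriNet, marking: Marking, role: str, config: SimulationConfig) -> Marking:
    ids = config.order(t.id for t in net.transitions.values() if t.role == role)
    for tid in ids:
        if is_enabled(net, tid, marking):
            marking = fire(net, tid, marking)
    return marking


def step_cycle(net: PetriNet, marking: Marking, k: int, config: SimulationConfig) -> Marking:
    """Execute one unit cycle [k, k+1): decays, then processes, then generation."""
    marking = _phase(net, marking, DECAY, config)
    marking = _phase(net, marking, PROCESS, config)
    marking = _phase(net, marking, GENERATION, config)
    return marking


def simulate(net: PetriNet, config: SimulationConfig | None = None) -> SimulationResult:
    """Run the delay-ordered simulation for ``config.horizon`` time units."""
    config = config or SimulationConfig()
    problems = validate_net(net)
    if problems:
        raise ValidationError("refusing to simulate an invalid net: " + "; ".join(problems))
    marking = net.initial_marking()
    times = [0]
    trajectory = [dict(marking)]
    for k in range(config.horizon):
        marking = step_cycle(net, marking, k, config)
        times.append(k + 1)
        trajectory.append(dict(marking))
    finals = {p.name: marking[p.id] for p in net.result_places()}
    bound = {p.name: marking[p.id] for p in net.counter_places()}
    return SimulationResult(
        times=times,
        trajectory=trajectory,
        finals=finals,
        bound=bound,
        place_names={p.id: p.name for p in net.places.values()},
        place_roles={p.id: p.role for p in net.places.values()},
    )


# ---------------------------------------------------------------------------
# CSV export


def export_results(result: SimulationResult, path) -> None:
    """Write the finals summary: one row per result and counter place."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["place", "role", "tokens"])
        for name in sorted(result.finals):
            writer.writerow([name, "result", result.finals[name]])
        for name in sorted(result.bound):
            writer.writerow([name, "counter", result.bound[name]])


def export_trajectory(result: SimulationResult, path) -> None:
    """Write one row per place per integer time (long format)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "place", "tokens"])
        for t, marking in zip(result.times, result.trajectory):
            for pid in sorted(marking):
                writer.writerow([t, result.place_names.get(pid, pid), marking[pid]])


def read_finals(path) -> dict[str, dict[str, int]]:
    """Read a finals CSV back into {"result": {...}, "counter": {...}}."""
    out: dict[str, dict[str, int]] = {"result": {}, "counter": {}}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["role"], {})[row["place"]] = int(row["tokens"])
    return out
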