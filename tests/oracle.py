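"""Independent brute-force simulator used as a cross-check.

Naive time stepper at 0.1 resolution: it walks tenth-of-a-unit ticks and
fires any transition whose delay phase matches the tick, with its own
local implementation of enabling and firing.  It shares only the net data
model with the engine under test, not its scheduling or firing code.
"""

import math

from grnpetri.petrinet import INHIBITOR, Constant, MarkingOf, MinOf, PetriNet


def _raw(expr, marking):
    if isinstance(expr, Constant):
        return expr.value
    if isinstance(expr, MarkingOf):
        return marking[expr.place]
    if isinstance(expr, MinOf):
        return min(marking[expr.place_a], marking[expr.place_b])
    raise TypeError(expr)


def _in_weight(expr, marking):
    return max(math.ceil(_raw(expr, marking)), 1)


def _enabled(net: PetriNet, t, marking):
    if not t.active:
        return False
    for arc in net.arcs:
        if arc.target != t.id:
            continue
        w = _in_weight(arc.weight, marking)
        if arc.kind == INHIBITOR:
            if marking[arc.source] >= w:
                return False
        elif marking[arc.source] < w:
            return False
    return True


def _fire(net: PetriNet, t, marking):
    deltas = {}
    for arc in net.arcs:
        if arc.target == t.id and arc.kind != INHIBITOR:
            deltas[arc.source] = deltas.get(arc.source, 0) - _in_weight(arc.weight, marking)
        elif arc.source == t.id:
            deltas[arc.target] = deltas.get(arc.target, 0) + math.ceil(_raw(arc.weight, marking))
    for pid, d in deltas.items():
        marking[pid] += d
        assert marking[pid] >= 0, f"negative marking at {pid}"


def naive_simulate(net: PetriNet, horizon: int) -> dict:
    """Final marking after ``horizon`` time units at 0.1 tick resolution."""
    marking = {pid: p.start_tokens for pid, p in net.places.items()}
    for tick in range(1, horizon * 10 + 1):
        phase = tick % 10  # 1 = decay (delay 0.1), 7 = process (0.7), 0 = generation (1.0)
        due = sorted(
            t.id
            for t in net.transitions.values()
            if int(round(t.delay * 10)) % 10 == phase
        )
        for tid in due:
            t = net.transitions[tid]
            if _enabled(net, t, marking):
                _fire(net, t, marking)
    return marking
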