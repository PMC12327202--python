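"""Shared helpers for structural checks on transformed nets."""

from grnpetri.petrinet import COUNTER, DECAY, GENERATION, PROCESS, RESULT, Constant


def gene_subsystems(net):
    """Map each DNA pool place to its generation rate/activity, counters, and
    result places, derived purely from the net topology."""
    subsystems = {}
    for place in net.places.values():
        if place.role != "entity" or place.entity_type != "DNA":
            continue
        gen = [
            t
            for t in net.transitions.values()
            if t.role == GENERATION
            and any(a.source == t.id and a.target == place.id for a in net.arcs)
        ]
        assert len(gen) == 1
        rate_arcs = [a for a in net.arcs if a.source == gen[0].id and a.target == place.id]
        assert isinstance(rate_arcs[0].weight, Constant)
        processes = {
            a.target
            for a in net.arcs
            if a.source == place.id
            and a.target in net.transitions
            and net.transitions[a.target].role == PROCESS
        }
        results = {
            a.target
            for a in net.arcs
            if a.source in processes and net.places.get(a.target, None) is not None
            and net.places[a.target].role == RESULT
        }
        decays = {
            a.target
            for a in net.arcs
            if a.source == place.id
            and a.target in net.transitions
            and net.transitions[a.target].role == DECAY
        }
        counters = {
            a.target
            for a in net.arcs
            if a.source in decays and net.places.get(a.target) is not None
            and net.places[a.target].role == COUNTER
        }
        subsystems[place.id] = {
            "rate": int(rate_arcs[0].weight.value),
            "active": gen[0].active,
            "start": place.start_tokens,
            "results": results,
            "counters": counters,
        }
    return subsystems


def check_conservation(net, result):
    """Tokens generated into each gene pool equal bound + produced + residual
    at every integer time."""
    for pid, sub in gene_subsystems(net).items():
        for t, snapshot in zip(result.times, result.trajectory):
            generated = sub["start"] + (sub["rate"] * t if sub["active"] else 0)
            balance = (
                snapshot[pid]
                + sum(snapshot[c] for c in sub["counters"])
                + sum(snapshot[r] for r in sub["results"])
            )
            assert generated == balance, (
                f"conservation broken for {pid} at t={t}: generated {generated}, "
                f"accounted {balance}"
            )
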