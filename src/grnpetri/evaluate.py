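"""Coherence of simulation outcomes with differential expression.

Gene pairs sharing a targeting miRNA are classified by comparing each
gene's accumulated result tokens against its own and its partner's input
rate (the per-time-unit token generation, i.e. the CPM rounded up):
accumulation is *low* below both rates and *high* above both.  A
downregulated gene (log2FC < 0) with low accumulation — or an upregulated
gene with high accumulation — is *coherent* with the expression analysis;
the opposite combinations are *contradictory*.  Accumulations between the
two rates get no forced call and are reported as *indeterminate*.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

from . import grn as g
from .errors import PairingError, UnknownReferenceError
from .rules import result_place_name

LOW = "low"
HIGH = "high"
INDETERMINATE = "indeterminate"
COHERENT = "coherent"
CONTRADICTORY = "contradictory"


@dataclass
class CoherenceVerdict:
    gene: str
    partner: str | None
    log2fc: float
    accumulation: str
    verdict: str
    total_output: int
    input_rate: int
    partner_input_rate: int | None


def input_rate(network: g.GRN, gene: str) -> int:
    """Per-time-unit token generation of a gene: its CPM rounded up."""
    node = network.node(gene)
    if node.label != g.DNA:
        raise UnknownReferenceError(f"{gene!r} is not a gene (DNA) node")
    return math.ceil(node.start_concentration)


def gene_output(network: g.GRN, gene: str, finals: dict[str, int]) -> int:
    """Total result tokens over all of the gene's isoform result places."""
    isoforms = network.isoforms_of(gene)
    total = 0
    for transcript in isoforms:
        name = result_place_name(gene, transcript)
        if name not in finals:
            raise UnknownReferenceError(f"finals table lacks result place {name!r}")
        total += finals[name]
    return total


def classify_accumulation(
    gene: str, partner: str | None, finals: dict[str, int], network: g.GRN
) -> str:
    """Low iff below both input rates, high iff above both; else indeterminate.

    Singleton genes (no partner) compare against their own rate only.
    """
    total = gene_output(network, gene, finals)
    rates = [input_rate(network, gene)]
    if partner is not None:
        rates.append(input_rate(network, partner))
    if all(total < r for r in rates):
        return LOW
    if all(total > r for r in rates):
        return HIGH
    return INDETERMINATE


def _verdict(log2fc: float, accumulation: str) -> str:
    if accumulation == INDETERMINATE or log2fc == 0:
        return INDETERMINATE
    down = log2fc < 0
    if (down and accumulation == LOW) or (not down and accumulation == HIGH):
        return COHERENT
    return CONTRADICTORY


def shared_mirnas(network: g.GRN, gene_a: str, gene_b: str) -> list[str]:
    def mirna_set(gene):
        out = set()
        for transcript in network.isoforms_of(gene):
            out.update(network.targeting_mirnas(transcript))
        return out

    return sorted(mirna_set(gene_a) & mirna_set(gene_b))


def classify_gene(
    gene: str, partner: str | None, finals: dict[str, int], network: g.GRN
) -> CoherenceVerdict:
    accumulation = classify_accumulation(gene, partner, finals, network)
    node = network.node(gene)
    return CoherenceVerdict(
        gene=gene,
        partner=partner,
        log2fc=node.log2fc,
        accumulation=accumulation,
        verdict=_verdict(node.log2fc, accumulation),
        total_output=gene_output(network, gene, finals),
        input_rate=input_rate(network, gene),
        partner_input_rate=input_rate(network, partner) if partner else None,
    )


def classify_pair(
    gene_a: str, gene_b: str, finals: dict[str, int], network: g.GRN
) -> tuple[CoherenceVerdict, CoherenceVerdict]:
    """Per-gene verdicts for a pair of genes sharing >= 1 targeting miRNA."""
    if not shared_mirnas(network, gene_a, gene_b):
        raise PairingError(f"genes {gene_a!r} and {gene_b!r} share no targeting miRNA")
    return (
        classify_gene(gene_a, gene_b, finals, network),
        classify_gene(gene_b, gene_a, finals, network),
    )


def knockout_success(
    base_finals: dict[str, int], ko_finals: dict[str, int], transcript: str
) -> tuple[bool, int]:
    """A knockout is successful when the target transcript's result total rises.

    ``transcript`` may be a full result-place name or a transcript id
    matched inside one.  Returns (success, delta = knockout - baseline).
    """

    def lookup(finals):
        if transcript in finals:
            return finals[transcript]
        hits = [n for n in finals if f"_{transcript}_FINAL" in n or n.startswith(f"{transcript}_")]
        if len(hits) != 1:
            raise UnknownReferenceError(
                f"cannot resolve {transcript!r} to a unique result place (hits: {hits})"
            )
        return finals[hits[0]]

    base = lookup(base_finals)
    ko = lookup(ko_finals)
    delta = ko - base
    return delta > 0, delta


def write_verdicts(verdicts, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "gene",
                "partner",
                "log2fc",
                "input_rate",
                "partner_input_rate",
                "total_output",
                "accumulation",
                "verdict",
            ]
        )
        for v in verdicts:
            writer.writerow(
                [
                    v.gene,
                    v.partner or "",
                    v.log2fc,
                    v.input_rate,
                    v.partner_input_rate if v.partner_input_rate is not None else "",
                    v.total_output,
                    v.accumulation,
                    v.verdict,
                ]
            )
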