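"""Biological gene regulatory network (GRN) model.

The networks modeled here describe post-transcriptional regulation: gene
(DNA) nodes produce alternative-polyadenylation transcript isoforms (mRNA
nodes), and miRNA nodes inhibit specific isoforms through 3'UTR target
sites.  Every node carries a start concentration (library-normalized read
count, CPM), a log2 fold change relative to the pluripotent baseline, and a
color encoding the direction of differential expression.  Edges are typed
"Physical Interaction" and are either parentage (DNA -> mRNA) or targeting
(miRNA -> mRNA).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import GraphMLError, UnknownReferenceError, ValidationError

DNA = "DNA"
MIRNA = "miRNA"
MRNA = "mRNA"
NODE_LABELS = frozenset({DNA, MIRNA, MRNA})

#: Edge label used for every regulatory connection.
EDGE_LABEL = "Physical Interaction"

#: Differential-expression color scheme.  Genes are blues, miRNAs purples;
#: the shade follows the log2FC sign (dark = upregulated, light =
#: downregulated).  Transcript isoforms always get the dark navy default.
#: The |log2FC| <= 2 mid shades only occur in user-supplied networks; the
#: differential-expression filter upstream keeps only |log2FC| > 2 nodes.
COLOR_SCHEME = {
    (DNA, "up"): "#00008B",
    (DNA, "down"): "#ADD8E6",
    (DNA, "mid"): "#4169E1",
    (MIRNA, "up"): "#4B0082",
    (MIRNA, "down"): "#C9A0DC",
    (MIRNA, "mid"): "#9370DB",
    MRNA: "#000080",
}

_LOG2FC_DARK = 2.0
_LOG2FC_LIGHT = -2.0


@dataclass
class GRNNode:
    """A node of the regulatory network.

    ``start_concentration`` is in CPM and mandatory (and > 0) for DNA and
    miRNA nodes; mRNA nodes may or may not carry one (when a gene has
    several isoforms, one isoform is chosen at random to carry the gene's
    concentration attribute — the value is stored but plays no role in the
    Petri net transformation, which consumes the DNA node's concentration).
    """

    id: str
    name: str
    label: str
    start_concentration: float | None = None
    log2fc: float | None = None
    color: str = ""

    def validate(self) -> list[str]:
        problems = []
        if self.label not in NODE_LABELS:
            problems.append(
                f"node {self.id!r}: label {self.label!r} not in {sorted(NODE_LABELS)}"
            )
        if self.label in (DNA, MIRNA):
            # concentration 0 is allowed and means no expression (knockout)
            if self.start_concentration is None:
                problems.append(f"node {self.id!r}: {self.label} node lacks a start concentration")
            elif self.start_concentration < 0:
                problems.append(
                    f"node {self.id!r}: start concentration must be >= 0, got {self.start_concentration}"
                )
        if self.start_concentration is not None and self.start_concentration < 0:
            problems.append(f"node {self.id!r}: negative start concentration")
        return problems


@dataclass
class GRNEdge:
    """Directed regulatory connection; ``kind`` is derived from node labels."""

    source: str
    target: str
    label: str = EDGE_LABEL


PARENTAGE = "parentage"
TARGETING = "targeting"


@dataclass
class GRN:
    """An attributed, directed gene regulatory network."""

    nodes: dict[str, GRNNode] = field(default_factory=dict)
    edges: list[GRNEdge] = field(default_factory=list)

    # -- accessors ---------------------------------------------------------

    def node(self, node_id: str) -> GRNNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise UnknownReferenceError(f"no node with id {node_id!r}") from None

    def edge_kind(self, edge: GRNEdge) -> str:
        src = self.node(edge.source)
        tgt = self.node(edge.target)
        if src.label == DNA and tgt.label == MRNA:
            return PARENTAGE
        if src.label == MIRNA and tgt.label == MRNA:
            return TARGETING
        raise ValidationError(
            f"edge {edge.source!r}->{edge.target!r} connects {src.label} to {tgt.label}; "
            "only DNA->mRNA and miRNA->mRNA edges are allowed"
        )

    def genes(self) -> list[GRNNode]:
        return [n for n in self.nodes.values() if n.label == DNA]

    def mirnas(self) -> list[GRNNode]:
        return [n for n in self.nodes.values() if n.label == MIRNA]

    def transcripts(self) -> list[GRNNode]:
        return [n for n in self.nodes.values() if n.label == MRNA]

    def parent_of(self, transcript_id: str) -> str:
        parents = [
            e.source
            for e in self.edges
            if e.target == transcript_id and self.nodes[e.source].label == DNA
        ]
        if len(parents) != 1:
            raise ValidationError(
                f"transcript {transcript_id!r} has {len(parents)} parent genes, expected 1"
            )
        return parents[0]

    def isoforms_of(self, gene_id: str) -> list[str]:
        self.node(gene_id)
        return sorted(
            e.target
            for e in self.edges
            if e.source == gene_id and self.nodes[e.target].label == MRNA
        )

    def targets_of(self, mirna_id: str) -> list[str]:
        """Transcript ids targeted by a miRNA, sorted for determinism."""
        self.node(mirna_id)
        return sorted(e.target for e in self.edges if e.source == mirna_id)

    def targeting_mirnas(self, transcript_id: str) -> list[str]:
        return sorted(
            e.source
            for e in self.edges
            if e.target == transcript_id and self.nodes[e.source].label == MIRNA
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> list[str]:
        """Collect structural invariant violations (empty list = valid)."""
        problems: list[str] = []
        for node in self.nodes.values():
            problems.extend(node.validate())
        parent_count: dict[str, int] = {n.id: 0 for n in self.transcripts()}
        for edge in self.edges:
            if edge.source not in self.nodes or edge.target not in self.nodes:
                problems.append(f"edge {edge.source!r}->{edge.target!r} references a missing node")
                continue
            src = self.nodes[edge.source]
            tgt = self.nodes[edge.target]
            if tgt.label != MRNA or src.label not in (DNA, MIRNA):
                problems.append(
                    f"edge {edge.source!r}->{edge.target!r} connects {src.label} to {tgt.label}"
                )
            elif src.label == DNA:
                parent_count[edge.target] += 1
        for tid, k in parent_count.items():
            if k != 1:
                problems.append(f"transcript {tid!r} has {k} parent genes, expected exactly 1")
        return problems

    def require_valid(self) -> "GRN":
        problems = self.validate()
        if problems:
            raise ValidationError("; ".join(problems))
        return self

    def copy(self) -> "GRN":
        return GRN(
            nodes={nid: replace(n) for nid, n in self.nodes.items()},
            edges=[replace(e) for e in self.edges],
        )


# ---------------------------------------------------------------------------
# construction from tabular inputs


def _as_frame(table, columns: Sequence[str]) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        missing = [c for c in columns if c not in table.columns]
        if missing:
            raise ValidationError(f"table lacks required columns {missing}")
        return table
    rows = list(table) if table is not None else []
    if rows and isinstance(rows[0], Mapping):
        frame = pd.DataFrame(rows)
        missing = [c for c in columns if c not in frame.columns]
        if missing:
            raise ValidationError(f"table lacks required columns {missing}")
        return frame
    return pd.DataFrame(rows, columns=list(columns))


def build_grn(genes, isoforms, mirnas, targets, seed: int = 0) -> GRN:
    """Assemble a validated GRN from four tables.

    Parameters
    ----------
    genes : table of (symbol, cpm, log2fc)
    isoforms : table of (transcript_id, parent_symbol)
    mirnas : table of (name, cpm, log2fc)
    targets : table of (mirna_name, transcript_id)
    seed : int
        Seeds the random choice of which isoform carries the gene-level
        concentration attribute when a gene has more than one isoform.

    Transcript log2FC is inherited from the parent gene.  Each gene must
    have at least one isoform and every reference must resolve.
    """
    genes = _as_frame(genes, ("symbol", "cpm", "log2fc"))
    isoforms = _as_frame(isoforms, ("transcript_id", "parent_symbol"))
    mirnas = _as_frame(mirnas, ("name", "cpm", "log2fc"))
    targets = _as_frame(targets, ("mirna_name", "transcript_id"))

    if genes["symbol"].duplicated().any():
        dupes = sorted(genes.loc[genes["symbol"].duplicated(), "symbol"])
        raise ValidationError(f"duplicate gene symbols: {dupes}")
    if isoforms["transcript_id"].duplicated().any():
        dupes = sorted(isoforms.loc[isoforms["transcript_id"].duplicated(), "transcript_id"])
        raise ValidationError(f"duplicate transcript ids: {dupes}")
    if mirnas["name"].duplicated().any():
        dupes = sorted(mirnas.loc[mirnas["name"].duplicated(), "name"])
        raise ValidationError(f"duplicate miRNA names: {dupes}")

    grn = GRN()
    for row in genes.itertuples(index=False):
        grn.nodes[row.symbol] = GRNNode(
            id=row.symbol,
            name=row.symbol,
            label=DNA,
            start_concentration=float(row.cpm),
            log2fc=float(row.log2fc),
        )
    for row in mirnas.itertuples(index=False):
        if row.name in grn.nodes:
            raise ValidationError(f"node id {row.name!r} used for both a gene and a miRNA")
        grn.nodes[row.name] = GRNNode(
            id=row.name,
            name=row.name,
            label=MIRNA,
            start_concentration=float(row.cpm),
            log2fc=float(row.log2fc),
        )

    gene_log2fc = {row.symbol: float(row.log2fc) for row in genes.itertuples(index=False)}
    gene_cpm = {row.symbol: float(row.cpm) for row in genes.itertuples(index=False)}
    by_gene: dict[str, list[str]] = {}
    for row in isoforms.itertuples(index=False):
        if row.parent_symbol not in gene_log2fc:
            raise UnknownReferenceError(
                f"isoform {row.transcript_id!r} references unknown gene {row.parent_symbol!r}"
            )
        if row.transcript_id in grn.nodes:
            raise ValidationError(f"transcript id {row.transcript_id!r} collides with another node")
        grn.nodes[row.transcript_id] = GRNNode(
            id=row.transcript_id,
            name=row.transcript_id,
            label=MRNA,
            log2fc=gene_log2fc[row.parent_symbol],
        )
        grn.edges.append(GRNEdge(source=row.parent_symbol, target=row.transcript_id))
        by_gene.setdefault(row.parent_symbol, []).append(row.transcript_id)

    missing = sorted(set(gene_log2fc) - set(by_gene))
    if missing:
        raise ValidationError(f"genes without any isoform: {missing}")

    # one isoform per gene carries the gene-level concentration attribute;
    # the draw is seeded so the same inputs always yield the same network
    rng = np.random.default_rng(seed)
    for symbol in sorted(by_gene):
        isos = sorted(by_gene[symbol])
        chosen = isos[0] if len(isos) == 1 else isos[int(rng.integers(len(isos)))]
        grn.nodes[chosen].start_concentration = gene_cpm[symbol]

    for row in targets.itertuples(index=False):
        if row.mirna_name not in grn.nodes or grn.nodes[row.mirna_name].label != MIRNA:
            raise UnknownReferenceError(f"target references unknown miRNA {row.mirna_name!r}")
        if row.transcript_id not in grn.nodes or grn.nodes[row.transcript_id].label != MRNA:
            raise UnknownReferenceError(
                f"target references unknown transcript {row.transcript_id!r}"
            )
        grn.edges.append(GRNEdge(source=row.mirna_name, target=row.transcript_id))

    return assign_colors(grn).require_valid()


# ---------------------------------------------------------------------------
# colors


def node_color(label: str, log2fc: float | None) -> str:
    """Color code for a node: a pure function of (label, log2FC)."""
    if label == MRNA:
        return COLOR_SCHEME[MRNA]
    if log2fc is None:
        raise ValidationError(f"{label} node lacks a log2FC value for color assignment")
    if log2fc > _LOG2FC_DARK:
        shade = "up"
    elif log2fc < _LOG2FC_LIGHT:
        shade = "down"
    else:
        shade = "mid"
    return COLOR_SCHEME[(label, shade)]


def assign_colors(grn: GRN) -> GRN:
    """Return a copy of the GRN with differential-expression colors set."""
    out = grn.copy()
    for node in out.nodes.values():
        node.color = node_color(node.label, node.log2fc)
    return out


# ---------------------------------------------------------------------------
# GraphML (de)serialization

#: GraphML node attribute keys.
_KEY_NAME = "name"
_KEY_LABEL = "label"
_KEY_CONC = "concentration"
_KEY_LOG2FC = "log2FC"
_KEY_COLOR = "color"
_MANDATORY = (_KEY_NAME, _KEY_LABEL, _KEY_LOG2FC, _KEY_COLOR)


def to_networkx(grn: GRN) -> nx.DiGraph:
    g = nx.DiGraph()
    for node in grn.nodes.values():
        attrs = {
            _KEY_NAME: node.name,
            _KEY_LABEL: node.label,
            _KEY_LOG2FC: float(node.log2fc) if node.log2fc is not None else float("nan"),
            _KEY_COLOR: node.color,
        }
        if node.start_concentration is not None:
            attrs[_KEY_CONC] = float(node.start_concentration)
        g.add_node(node.id, **attrs)
    for edge in grn.edges:
        g.add_edge(edge.source, edge.target, label=edge.label)
    return g


def from_networkx(g: nx.Graph) -> GRN:
    grn = GRN()
    for node_id, data in g.nodes(data=True):
        for key in _MANDATORY:
            if key not in data:
                raise GraphMLError(f"node {node_id!r} lacks mandatory attribute key {key!r}")
        label = data[_KEY_LABEL]
        conc = data.get(_KEY_CONC)
        if label in (DNA, MIRNA) and conc is None:
            raise GraphMLError(f"{label} node {node_id!r} lacks the {_KEY_CONC!r} key")
        grn.nodes[str(node_id)] = GRNNode(
            id=str(node_id),
            name=str(data[_KEY_NAME]),
            label=str(label),
            start_concentration=float(conc) if conc is not None else None,
            log2fc=float(data[_KEY_LOG2FC]),
            color=str(data[_KEY_COLOR]),
        )
    for src, tgt, data in g.edges(data=True):
        grn.edges.append(GRNEdge(source=str(src), target=str(tgt), label=data.get("label", EDGE_LABEL)))
    return grn


def write_graphml(grn: GRN, path) -> None:
    nx.write_graphml(to_networkx(grn), path, encoding="utf-8")


def read_graphml(path) -> GRN:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # networkx raises lxml/ElementTree errors directly
        raise GraphMLError(f"cannot parse GraphML file {path}: {exc}") from exc
    return from_networkx(g)
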