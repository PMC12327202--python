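# Methods

## Model

The package models post-transcriptional regulation as a functional Petri
net (FPN) with inhibitor arcs — a subset of hybrid functional Petri nets
restricted to discrete places, deterministic delays, and marking-dependent
arc weights. Tokens are transcript counts on the CPM scale; places are
molecular pools (gene transcripts awaiting processing, free miRNA) or
bookkeeping devices (counters of bound-and-decayed pairs, result places of
produced isoforms); transitions are processes (constant-rate generation,
miRNA–mRNA binding/decay, isoform production).

The model's biological assumptions, inherited from the transformation
rules, are:

1. transcripts are generated at a constant per-time-unit rate ⌈CPM⌉;
2. a single remaining miRNA token fully inhibits an isoform's production,
   regardless of stoichiometry;
3. the minimum of available miRNA and gene tokens binds and decays first
   every cycle;
4. all gene tokens remaining after binding are then produced by each
   uninhibited isoform process.

No RNA half-life, translation, transcription factors, lncRNA sponging, or
per-molecule inhibition capacity is modeled.

## Firing schedule and conflict resolution

The delays (decay 0.1, process 0.7, generation 1.0) induce a strict phase
order inside each unit cycle k: all decays at k+0.1, all processes at
k+0.7, all generations at k+1. Cycle 0 runs on the start tokens (equal to
the generation rates), and a horizon of T time units therefore contains
exactly T production opportunities — this is the only schedule consistent
with the worked examples (20 × (179−13−50) = 2,320).

Within a phase, transitions fire at most once each, in lexicographic id
order unless an explicit priority list is given; enablement is re-checked
before each firing because functional weights change as earlier firings
consume tokens. Two conflict situations exist:

- **Decays of one gene.** The order never changes any result total: if the
  cycle's total miRNA demand fits into the gene pool, every decay binds its
  full minimum in any order; if it does not, the pool is exhausted and some
  miRNA residue survives in every order, which keeps the processes
  inhibited and the increment at zero. The test suite verifies this
  exhaustively over all decay permutations on nets with up to three
  miRNAs.
- **Cross-gene competition** (one miRNA pool binding into several genes,
  or several isoform processes draining one gene pool) **is** order
  dependent when supply is scarce. The lexicographic default is a
  documented convention chosen for determinism, not a biological claim;
  it is configurable through `SimulationConfig.priority`.

Decay transitions firing once per phase is not a restriction: a firing
exhausts one side of its min(), after which the transition is disabled, so
re-firing within a cycle would be a no-op. Unbound miRNA persists across
cycles (binding is the only miRNA sink), which can only prolong
inhibition and never changes a result total in single-gene subsystems.

## Sanitization and degenerate inputs

Every weight is rounded up to an integer (`ceil`), and weights on arcs
into a transition are clamped to `max(f, 1)`. The clamp is what disables a
decay whose miRNA pool is empty — min(0, d) would otherwise allow a free
firing — and what disables a process whose gene pool is empty. Start
concentrations are accepted down to 0: a zero-concentration gene or miRNA
is transformed into a pool whose feeding transition is created deactivated,
which makes "set concentration to 0, then transform" exactly equivalent to
an in silico knockout of the transformed net. (Knockout itself deactivates
the generation transition *and* zeroes the start tokens; leaving the start
tokens would let one residual round bind in cycle 0 and change the IGFBP7
knockout total from 3,320 to 3,270.)

Markings are integers throughout; the engine asserts non-negativity at
every firing. An invalid net (dangling arc endpoint, non-bipartite arc,
inhibitor arc with weight ≠ 1 or wrong direction) is refused before
simulation with a full violation report rather than a first-error throw.

## Transformation choices

Element ids are derived deterministically from GRN ids
(`P_DNA_<gene>`, `P_MIR_<mirna>`, `T_GEN_<node>`, `T_MRNA_<transcript>`,
`T_DECAY_<mirna>_<gene>`, `P_CNT_<mirna>_<gene>`,
`P_<GENE>_<TRANSCRIPT>_FINAL`), so transformation is reproducible and
provenance is invertible. Decay transitions are created per (miRNA, gene)
pair, not per targeting edge: duplicate decays for a miRNA targeting
several isoforms of one gene are provably output-equivalent (the first
firing exhausts one side of the min) but would inflate the net. Each decay
gets its own counter place; counters report the cumulative number of
bound-and-removed token pairs ("bound" in the results).

When a gene has several isoforms, one isoform — chosen by a seeded random
draw — additionally carries the gene's concentration attribute. The value
is stored and round-trips through GraphML but is deliberately unused by
the transformation, which consumes only the DNA node's concentration; the
attribute exists for interchange fidelity with networks built elsewhere.

## Coherence evaluation

A gene's "input" is its per-time-unit generation rate ⌈CPM⌉, and its
"output" is the sum over its isoforms' result places after the simulation.
Output below both the gene's and its partner's input is *low*; above both
is *high*. Low + downregulated (log2FC < 0) and high + upregulated are
*coherent*; the crossed combinations are *contradictory*. An output that
falls between the two inputs satisfies neither definition and is reported
as *indeterminate* rather than forced into a verdict. Interpreting
"input" as the per-unit rate (not the T-fold cumulative supply) is what
makes the published calls come out as printed (e.g. 480 > 25 and 281 →
high for a 20-unit run).

## Synthetic data

`generate_grn` draws networks with the structure the method assumes: every
gene has ≥ 1 isoform, miRNAs target isoforms independently with a fixed
probability, CPM values are log-normal (default median ≈ 90, a typical
magnitude for the expressed genes in the worked examples), and log2FC
values are a signed normal shifted past the |2| differential-expression
cutoff, because the networks the method operates on contain only
differentially expressed nodes. The generator emulates network *topology
and attribute ranges* only — not read-count noise, isoform-length
structure, shared-seed targeting correlations, or the heavy-tailed degree
distributions of real miRNA target networks — so passing property tests
demonstrates correctness of the transformation/simulation machinery, not
biological realism of any particular random net.

The `paper_fixture` networks reconstruct published worked examples from
their printed concentrations. They are isolated pair-subnetworks: the
deposited day networks contain additional targeting edges shown only in
figures, so a fixture reproduces exactly the totals that follow from the
printed values and documents the rest. In particular `mad2l2_sephs1_d9p`
reproduces MAD2L2's zero accumulation but not SEPHS1's (the deposited
network targets SEPHS1 with 9 miRNAs, of which the text names one at
1 CPM), and `aass_d4p_core` cannot reproduce the published 0/20 per-isoform
split. Transcript accessions the source text does not print use synthetic
`SYMBOL-2xx` placeholders.

## Verification

The engine is cross-checked against an independent naive event simulator
(tests/oracle.py) that walks 0.1-time-unit ticks with its own enabling and
firing code; both must agree on the complete final marking on every
fixture and on batches of random nets. Further invariants under test:
per-gene token conservation (generated = bound + produced + residual at
every integer time), monotone non-decreasing result and counter places,
decay-order invariance within a gene, knockout monotonicity (result totals
never decrease), and the uninhibited closed form total = T × ⌈CPM⌉.
Property tests run on deliberately small networks (≈ 3 genes, ≈ 3 miRNAs,
horizons of 4–10 time units), which keeps the whole suite in the
seconds range while exercising every conflict pattern the semantics
distinguish; the worked-example checks always run the full 20-unit
horizon.

## Limitations

- Inhibition is all-or-nothing per remaining miRNA token; partial
  (anti-miRNA-style) suppression is not modeled — only full knockout and
  concentration changes.
- Cross-gene competition outcomes depend on the configured conflict order
  when supply is scarce (see above).
- Continuous and stochastic Petri net semantics are out of scope; the
  engine is integer-exact by design.
- SBML import/export of the deposited networks is not implemented; the
  native interchange formats are GraphML (GRN) and JSON (Petri net).
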