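# Methods

This note records the model behind `phenolink`, the parameters that matter,
the numerical and design choices made where the design was open, and what
the synthetic data does and does not establish.

## Data model

An observation is four things: a target (patient), a feature (a coded
variable), a protocol, and a value. Patients are collections of
time-stamped observations; all semantics beyond that live in the
terminology, not in the object model. Loading is strictly separated from
transformation (extract, *load*, then transform): original codes are kept
verbatim and concept annotations are derived in a repeatable step, so the
mapping can be regenerated whenever the terminology is updated without
touching the source data. One observation may carry several concepts
(overcoding) — annotation is a set, not a field.

Timestamps are parsed and preserved but not used in queries; temporal and
value-restricted querying is out of scope.

## Terminology store

The store accepts the full 18-column MRCONSO layout and a minimal 8-column
layout (`CUI|LAT|AUI|SAB|TTY|CODE|STR|SUPPRESS`), auto-detected by column
count; similarly for relations (16 or 5 columns), semantic types (6 or 3)
and attributes (13 or 4). Only English atoms are indexed. Suppressed atoms
(`SUPPRESS ∈ {O, E, Y}`) are excluded by default and retained with an
`obsolete` flag when requested — the crosswalk needs them to report
retired-code reactivation. Relation rows are normalized to a single
internal child → parent direction (`PAR`: second concept is the parent;
`CHD`: the inverse). A concept's preferred label is the label of its first
non-suppressed atom under a fixed source-priority order then atom id; the
choice is arbitrary but deterministic.

The hierarchical view admits an edge iff it is a PAR/CHD relation asserted
by an allowed source (default: MTH, SNOMEDCT, LNC, RXNORM, NDFRT, HCPCS,
ICD9CM, ICD10CM) or its (source, rela) pair is configured as augmentation
(default: LNC `class_of`, LNC `measured_by`, RXNORM `has_ingredient`).
Restricting traversal avoids nonsensical cross-terminology paths; the
augmentation set gives the flat LOINC/RxNorm hierarchies useful parents
(a warfarin-concentration test becomes a child of Warfarin). Cycles are
preserved in the view and handled downstream.

## Search

Atom strings are lowercased and split on non-alphanumerics; no stop words
are removed, because idf(t) = ln(N/df(t)) already drives ubiquitous tokens
toward zero weight. Five tiers are evaluated in order, each result
surfacing once at its best tier, ranked within a tier by summed idf of
matched tokens, then label, then atom id:

1. **exact phrase** — query tokens contiguous and in order;
2. **proximity** — all tokens within a sliding window of 5 atom tokens
   (order-insensitive; the window width is a package choice);
3. **all tokens** — every query token present somewhere;
4. **accumulate** — a *strict majority* of query tokens present, the rest
   ignored;
5. **relaxed** — per-token Damerau–Levenshtein distance ≤ 2 for tokens of
   length ≥ 5 (≤ 1 otherwise), Porter-stem equality, and prefix expansion
   of the final query token.

The majority threshold for tier 4 (rather than ≥ 1 token) is deliberate:
with a ≥ 1 threshold a two-token typo query such as "cron disease" would
surface every label containing "disease" at the accumulate tier, and typo
recoveries could never rank at the fuzzy tier where they belong. With the
majority rule, a label matching 3 of 4 query tokens still accumulates,
while single-token coincidences fall through to tier 5.

Strict tier ordering is an approximation: the original interleaving of
relaxation operators inside a commercial text engine is not reproducible,
and its fuzzy matcher is more aggressive than per-token edit distance (it
can, e.g., relate "myleoid" to "myelofibrosis"; ours cannot). Later tiers
are skipped once `max_results` is filled by earlier ones, which keeps the
vocabulary scan of tier 5 off the common path.

## Expansion, condensation, propagation

Expansion walks all ancestor paths of a concept in the restricted view and
keeps ancestors whose semantic-type set intersects the *origin's*
(never the previous node's). Exclusion filters emission but not traversal:
a high-level ancestor reachable only through a differently-typed
intermediate is still expanded. A concept with no semantic types cannot be
compared and expands to nothing, with a warning. Excluded ancestors are
reported with their reason; within the restricted view the only applicable
reason is a semantic-type mismatch (edges from non-allowed sources never
enter the view in the first place).

Overlapping source hierarchies produce cycles, so the view is condensed by
strongly connected components (via networkx) into a DAG whose supernodes
are named by their lexicographically smallest member CUI. Patient-set
propagation then accumulates *sets* of patient identifiers bottom-up in
topological order: `patients(c)` is the union over c and its descendant
supernodes of the patients annotated there (direct, expanded, or
complement provenance alike). Because sets union idempotently, duplicate
annotations and parallel multi-parent paths cannot inflate counts — the
count at any concept is the number of distinct patients, full stop.
Annotations to concepts absent from the terminology are kept, counted at
that concept, and reported as orphan annotations.

Complements are taken per concept against the universe U of patients with
at least one propagated annotation (not all patients in the input file):
`complement(c) = U ∖ patients(c)`. Value-set complements are a separate,
earlier mechanism: for a positive/negative pair (e.g. deep venous
thrombosis / no past history of venous thrombosis), a patient annotated to
neither member gains the negative member with provenance `complement`.
The governing sentence in the source material is grammatically ambiguous
about who receives the negation; this package adds it to patients *lacking*
the condition, which is the only reading consistent with the negative
concepts' meaning, and tags it with its own provenance so the decision is
recoverable.

## Compaction and navigation

Hub ranking sorts concepts by (source count, branching factor) descending,
ties by CUI. The two quantities are combined lexicographically because
cross-source occurrence is the stated relevance hypothesis; no weighted
combination is attempted. Entry points take the top n ranked concepts per
listed source, collapse overlaps, and return the parentless nodes of the
induced subgraph.

The data-driven perspective approximates a minimum Steiner tree over the
condensed hierarchy viewed as an undirected unit-weight graph, using the
classic nearest-terminal shortest-path heuristic (a 2-approximation):
start from the lexicographically smallest terminal, repeatedly attach the
nearest unconnected terminal along a BFS shortest path with neighbor
expansion in sorted order, so output is deterministic. Each connected
component of terminals is rooted at the tree node with no hierarchy parent
inside the tree (smallest CUI on ties) and oriented child → parent.
Terminals that are absent from the DAG or isolated in it are orphans; a
reserved `ROOT` node anchors orphans and all component roots so the output
is always a single tree.

The browser view returns the active concept's parents, siblings (children
of its parents, including itself), and children, each carrying its
propagated patient count and a has-children flag; a root's sibling pane
contains only itself.

## Synthetic data

The reference fixture encodes the documented worked material: the
thrombosis neighborhood with its semantic types (Venous Thrombosis is
typed Pathologic Function and is therefore excluded from a Disease or
Syndrome expansion, while an ancestor reachable only through it is not),
the ICD-10-CM atom I82.40 on the thrombosis concept, an active/retired
ICD-9-CM atom pair for reactivation, the bronchitis multi-parent motif,
the search labels, the eight-member smoking value set, the DVT/AMI
positive/negative pairs, and the local-code map for the simulator's
variables. Concepts whose published identifiers are unknown carry
synthetic `C9xxxxxx` identifiers and are documented as such.

The cohort generator emits, per patient: 10 baseline variables (sex, race,
smoker/DVT/AMI flags, CYP2C9 and VKORC1 genotypes, height, weight, body
surface area), one warfarin dose record per protocol day (default 90), and
INR measurements every third day (default 30). Defaults: sex 50/50; race
mix approximating a US cohort (White 0.70, African American 0.12, Asian
0.05, Native American 0.01, Pacific Islander 0.01, other/unknown 0.11);
CYP2C9 allele frequencies *1/*2/*3 = 0.80/0.12/0.08 and VKORC1 G/A =
0.60/0.40 paired under Hardy–Weinberg, roughly European-ancestry values
for the two warfarin pharmacogenes; event probabilities smoker 0.20,
DVT 0.10, AMI 0.05 (plausible anticoagulation-clinic prevalences). Doses
and INR values are bounded random walks, not a pharmacokinetic model: the
upstream simulator is treated as a black box, and this artifact only needs
realistic *structure* (codes, schedules, value types). Consequently a green
test establishes correct mapping, propagation and counting behavior — it
says nothing about warfarin dose–response, and the generators make no
attempt to reproduce production-scale annotation volumes.

All generators are pure functions of (configuration, seed); identical
inputs yield byte-identical files.

## Numerical and degenerate-input choices

- Ordering everywhere is made total: (tier, −score, label, atom id) in
  search; CUI-lexicographic in neighbor lists, supernode naming, Steiner
  tie-breaks, and serialized outputs.
- Empty inputs are valid where an identity makes sense (empty concept file
  → empty graph; empty terminal set → empty tree; query of zero tokens →
  empty result with a warning). Empty allowed-source sets and non-positive
  entry-point counts are configuration errors.
- Unmapped observation codes are never dropped; they carry status
  `unmapped` and appear in the coverage summary.
- Rows with unparseable timestamps are skipped with a logged warning;
  structurally malformed rows (wrong column counts, missing mandatory
  header columns) fail fast with file and line number.

## Known limitations

- The relaxed search tier cannot reproduce every hit of a
  commercial fuzzy matcher (see above); ranking of the reproducible hits
  matches the documented orderings.
- LOINC codes and parts are treated as ordinary atoms; no part-specific
  logic is implemented.
- Hierarchy provenance is tracked per edge, but expansion does not report
  ancestors that would have been reachable only through non-allowed
  sources, since those edges never enter the restricted view.
- The production-scale figures associated with the full licensed
  Metathesaurus (millions of concepts, tens of thousands of mapped codes)
  are not reproducible here and are not targeted by the test suite.
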