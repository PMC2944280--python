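# Methods

## Pathway formalization

A pathway is a named pair (G, P): a set of numeric gene identifiers
(NCBI Gene ID semantics) and a set of directed gene-gene relationships,
each labelled activate, inhibit or neutral. Neutral is used where the
source asserts interaction without sign — chiefly metabolic adjacency,
where two enzymes catalyze consecutive steps. This deliberately throws
away stoichiometry, compartments, complexes-as-entities and kinetic
detail: the target consumers are gene-set and gene-network expression
analyses, which only need membership and signed wiring.

Symbols standing for protein families or classes expand to gene level:
a relation between an m-gene class and an n-gene class becomes the full
m·n cross product with the same sign. All statistics operate on the
expanded relations. Expansion assumes the curator meant "every member
of A acts on every member of B"; where that is too generous the error
is visible in the provenance, not hidden.

Two identity conventions matter:

* **Within a pathway**, pairs are deduplicated on the directed
  (source, target, relation) triple. The same directed edge asserted
  with two different relations is kept as two records — source
  databases really do contain such contradictions, and collapsing them
  silently would pick a winner without evidence.
* **Across databases**, the overlap key is the *unordered* gene-id
  pair, ignoring relation and direction. Rationale: a pair asserted as
  activating by one source and inhibiting by another is the same
  biological claim curated inconsistently, and counting it as "not
  shared" would understate agreement for the wrong reason. Relation
  conflicts are surfaced at merge time instead (see below).

Self-pairs (a gene acting on itself) are retained; nothing in the
formalization forbids autoregulation.

Symbol resolution is a plain offline TSV table (symbol → gene id,
case-insensitive, many-to-many). A symbol mapping to several ids is
treated as an implicit group of all of them. Unmapped labels are
skipped with a warning rather than aborting the pathway: real diagrams
contain metabolites, free-text labels and decorations.

## GPML reading

GPML encodes a picture. Gene boxes carry pixel coordinates; arrows and
T-bars are drawn between *regions*, not between identified nodes, so
connectivity must be reconstructed geometrically:

1. **Node extraction.** Every DataNode of a gene-like type
   (GeneProduct, Protein, Complex, RNA) with Graphics coordinates
   becomes a spatial node; Entrez Xrefs give ids directly, otherwise
   the label goes through the mapping table. Both the CenterX/CenterY
   and X/Y attribute spellings are accepted. Metabolite and label nodes
   are excluded from the network.
2. **Spatial clustering.** Nodes whose centers lie closer than a
   threshold (default 100 px) are joined transitively; clusters are the
   connected components of this proximity graph (single linkage), so
   they always partition the node set and are invariant to translation
   and node order. Distance is Euclidean center-to-center — the
   simplest reading of a pixel threshold. Single linkage is the only
   transitive choice that yields a partition; it matches how curators
   draw stacks and grids of related genes. Explicit GPML Group
   memberships are honored as clusters verbatim; only ungrouped nodes
   are clustered spatially.
3. **Line resolution.** Each Line/Interaction is approximated by its
   first-to-last straight segment and extended as a ray beyond each
   endpoint, capped at the diagram diagonal. The nearest cluster
   bounding box on the end side becomes the target, on the start side
   the source; an endpoint already inside a box needs no extension.
   Ties (two boxes entered at the same ray parameter) break by
   centroid distance to the endpoint, then cluster order. Lines that
   reach no cluster on one side are skipped with a warning and counted
   in the parse report. Arrow-head vocabulary: Arrow → activate,
   TBar/T-Bar → inhibit, Line/Solid/absent → neutral; any other style
   is treated as neutral with a warning.
4. Cluster-to-cluster relations expand to gene-level cross products and
   are finalized into a pathway.

Curved or multi-anchor lines are handled only as their end-to-end
segment; this is a known approximation, and unresolved lines are
reported rather than guessed.

## KGML reading

KGML is explicit: entries carry gene lists, relations connect entries.
Relation subtype mapping: activation/expression → activate,
inhibition/repression → inhibit, anything unsigned (phosphorylation
without a sign, binding, missing subtype) → neutral; enzyme-enzyme
(ECrel) relations are metabolic adjacency and always neutral. The
three-relation formalization admits nothing finer, and the subtype
table documents the choice rather than discarding unsigned relations
outright. Organism-prefixed ids ("hsa:7157") are stripped to numbers;
entries from other taxa are skipped with a warning. Group entries
expand to the union of their components. When a document has no
relation elements at all, neutral enzyme pairs are derived from
reaction elements (product of one reaction equals substrate of
another).

## Pathway matching

Names are normalized before comparison: case-folded, whitespace
collapsed, and the organism boilerplate suffix ("- Homo sapiens
(human)") stripped. Generic words like "signaling" and "pathway" are
*not* stripped — they carry real signal in the longest-common-substring
score, exactly as curators wrote them.

**LCS matching.** All cross-database name pairs are scored by the
length of their longest common substring (O(n·m) dynamic program,
deterministic tie-breaks) and walked greedily, longest first, into a
one-to-one matching. A pair is eligible when the common substring
covers ≥ 80% of the shorter normalized name, or when an explicit
confirm-list accepts it; reject entries veto. The confirm-list is the
auditable stand-in for the curator's manual scan of the ranked list —
the human step becomes an input file, not a buried heuristic. Walking
the full ranked pair list, rather than each pathway's single best
candidate, prevents a generic fragment (" signaling pathway") from
shadowing an exact match slightly further down. Unmatched pathways form
the PU list; each is annotated with its best gene-overlap partner (PUM)
and that pairing's pair-overlap percentage.

**Overlap matching.** Gene-overlap and pair-overlap matchers use
greedy best-first one-to-one assignment on descending overlap count
(tie-break by normalized names). The pair matcher rejects pairings
sharing fewer than 20 interacting pairs by default — below that it
floods with false positives. The assignment procedure is a documented
choice; an optimal assignment is not implied by the greedy rule and is
out of scope.

Three comparison procedures quantify matcher behaviour: top-3 agreement
of LCS partners within the gene-overlap ranking (disagreements
adjudicated by pair-overlap percentage); the (gene %, pair %) scatter
of LCS-matched versus PU/PUM pathways; and agreement-with-LCS curves
over the top-k% of each overlap matcher's output.

## Agreement and comprehensiveness statistics

Agreement percentages divide the overlap count by the *per-metric
minimum* of the two set sizes (the gene denominator and the pair
denominator may come from different databases for the same row) and
round half-up to an integer. Half-up, not banker's rounding: 7.5%
prints as 8%. The arithmetic validates overlap ≤ min(set sizes) and
rejects corrupt inputs — published comparison tables contain at least
one cell violating this identity, and reproducing such a cell would
require reproducing a typo.

The pathway comprehensive score builds equivalence classes of pathways
by union-find over confirmed cross-database matches (unmatched
pathways are singletons); a database's score is the fraction of
classes it hosts. A class containing two pathways from one database
(possible through chained matches) is kept with a warning — it usually
flags near-duplicate entries, and dropping it would silently change
the universe size. The gene pair coverage score is the fraction of the
union of all canonical pair keys a database hosts. Venn-style class
counts per database combination are derivable from the same classes.

## Merging and the query store

Matched classes merge by union: every member's genes and pairs
survive, each pair carrying the set of asserted relations and the set
of contributing databases. A pair asserted with two distinct
*non-neutral* relations (activate vs inhibit) is recorded as a
relation conflict; neutral alongside a signed relation is
under-specification, not contradiction. Nothing is discarded: the
consumer decides how to resolve conflicts.

The store is a plain in-memory object with JSON persistence — an
explicit, reproducible replacement for a hosted cache. Global numeric
pathway ids are assigned sequentially in import order. Query outputs
(gene lookup, pathway search, interaction listing, diffs) are plain
JSON structures, ordered ascending by numeric id then
lexicographically, so serialization is byte-stable for fixed input
order. Pathway diffs serialize pairs as "SYM1_SYM2" with symbols in
ascending-id order, taking the first mapping row for each id.

## Synthetic data

The generators define the package's study conditions:

* `generate_databases` plants cross-database pathway pairs with exact
  requested gene- and pair-overlap counts. Gene-id blocks are disjoint
  between pathway pairs, so overlaps are exactly the planted ones;
  non-shared pairs are constrained to touch at least one non-shared
  gene, so pair overlap cannot drift. The default specification uses
  seven matched pathways of 46–203 genes and 78–778 pairs with gene
  agreement 39–84% and pair agreement 3–45% of the smaller set, plus
  three unmatched pathways — magnitudes chosen to mirror what is
  observed between large public curated sources — and the four name
  variant patterns those sources use ("X", "X Signaling",
  "X - Homo sapiens (human)", "X signaling pathway"). Manifest
  percentages are computed with independent inline arithmetic so the
  manifest can serve as an oracle for the metrics module.
* `generate_gpml` renders a pathway as a diagram whose parse provably
  recovers it: cluster centers are placed in convex position on a
  jittered circle (convexity guarantees the straight line between any
  two cluster boxes clears all others; the radius is sized so adjacent
  clusters stay beyond the clustering threshold node-to-node, and
  chord-to-third-cluster clearance R(1 − cos θ) stays above the box
  extent). Relation lines start and end just *outside* their clusters'
  boxes, so the parser's ray extension is genuinely exercised. Layouts
  are validated geometrically and re-jittered on failure; an impossible
  request raises. Cluster partitions whose implied relations are not
  complete cross products are rejected — no diagram could parse back
  to such a pathway.
* `generate_kgml` renders entries (optionally multi-gene, exercising
  expansion) and relations, with neutral pairs as ECrel.

What the synthetic data does **not** emulate: realistic pathway
topology (degree distributions, motifs), curved/anchored GPML lines,
nested groups, multi-segment metabolic routes, or noisy/partial symbol
mappings. Passing round trips therefore demonstrate the geometry and
expansion machinery, not robustness to every drawing habit found in
the wild.

All randomness flows from a single integer seed through
`random.Random`; coordinates are emitted at one-decimal precision and
manifests regenerate byte-for-byte under a fixed seed.

## Numerical and degenerate-input choices

* Percentage rounding: decimal half-up, validated overlap ≤ min.
* Clustering threshold comparison is strict (< 100 px merges).
* Ray-box intersection uses the slab method with a 1e-12 tolerance on
  axis-parallel directions; extension is capped at the diagram
  diagonal so resolution always terminates.
* Agreement on an empty gene or pair set is an error (undefined
  denominator), not zero.
* Empty groups, empty merge classes and unresolvable relation
  endpoints raise; unmapped standalone labels and unresolved lines
  skip with warnings.
* Matching and query outputs are deterministic given input order; all
  ties break through normalized names or ascending ids.

## Problem sizes used in the checks

The bundled checks run on deliberately small instances: planted
databases of 9 + 8 pathways (up to ~780 pairs per pathway), 20
diagram round trips of 4–10 genes, 200 random layouts of ≤ 12 nodes
against a brute-force clustering oracle, 1,000 random string pairs
against an all-substrings LCS oracle, and 50 random merge/diff
fixtures. These sizes exercise every code path while keeping the whole
suite in the low seconds; the algorithms are polynomial (the LCS
dynamic program and pairwise clustering are quadratic) and scale to
full database snapshots without modification.

## Known limitations

* Diagram semantics beyond straight lines (anchors, elbows, ports) are
  approximated; affected lines are reported, not silently guessed.
* The 100-px threshold is a single global constant; diagrams drawn at
  unusual densities would need it re-tuned.
* One-to-one matching cannot express a pathway legitimately split
  across several entries in another database (many-to-many mappings
  are out of scope).
* Equivalence classes inherit any error in confirmed matches;
  union-find has no mechanism to reject a chain it was given.
* Relation subtype mapping for KGML collapses all unsigned biochemistry
  onto neutral.
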