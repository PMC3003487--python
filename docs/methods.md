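# Methods

## The network model

A curated regulation network is a *binary network*: links connect exactly
two genes/proteins, with no multi-partner reactions, no logic gates
("A AND B activate C"), no metabolites and no modification states.  A node
stands for both a gene and its protein product; node labels are MGI-style
gene symbols and are matched **case-sensitively** (mouse and human symbol
conventions differ only in case).  The three link types carry fixed
Systems Biology Ontology activity-flow terms — stimulation SBO:0000170,
inhibition SBO:0000169, interaction SBO:0000231 — and stimulation and
inhibition are directed while interaction is undirected.

Every link is a curation record: endpoints, type, one or more literature
references (PubMed ID + citation text), curator initials, date added.
Validation (`validate_link_record`) checks only the machine-checkable
parts of the curation rules — presence of references and curator, digit
PubMed IDs, known type, no self-loop.  The substantive curation criteria
(the mechanism is *direct*, and was shown in the mouse model system) are
properties of the cited literature and are documented as uncheckable.

Link identity (`canonical_link_key`) is configurable: interactions always
compare undirected; directed types keep their direction unless direction
is ignored; the type can be erased.  Exact duplicates (same endpoints,
direction, type) are merged at assembly time with reference lists unioned,
matching the convention that a link may list several supporting
publications.  Self-loops are rejected by default.  Interaction links keep
the endpoint order of their source file (round-trip fidelity) but compare
unordered.

## Topology

All statistics are computed on the **simple projection**: every link is
treated as undirected, parallel links between a pair collapse to one edge,
self-loops are dropped, isolated nodes are kept.  Average degree is
reported on this projection, not on raw link records — collapsing parallel
links is what standard network-analysis tools do when fed a typed
multigraph, and the two counts differ whenever curated parallel links
exist.  Conventions, stated so the numbers are reproducible:

* local clustering is `2·e_N / (k(k−1))` with value 0 for degree < 2, and
  the network coefficient averages over *all* nodes (degree-<2 nodes
  contribute 0); a flag restricts the average to degree-≥2 nodes,
  since analysis tools differ here.
* characteristic path length is the mean shortest-path distance over
  **connected unordered pairs**; disconnected pairs are excluded rather
  than treated as infinite (curated networks routinely contain small
  disconnected subnetworks).
* diameter is the largest finite distance.  Both are undefined (None) on
  edgeless graphs.

Graph algorithms run on networkx; the test suite cross-checks them against
an independent brute-force oracle (hand-written BFS and neighbor-pair
enumeration) on hundreds of seeded random graphs.

## Enrichment

Overrepresentation of a study set (typically the network's gene list)
against an annotated background uses the upper-tail hypergeometric test
`P(X ≥ k)` with BH step-up FDR correction across all tested terms (terms
with ≥ 1 study gene).  The background defaults to all annotated genes and
is configurable.  Annotations are read from two-column TSV or GAF 2.x
(NOT-qualified rows skipped); term names can be attached from OBO.  Term
propagation to ancestors is off by default — GO-slim annotation sets are
already collapsed to high-level terms — and available explicitly.
Adjusted p-values are clamped to be ≥ raw p-values so the dominance
invariant holds exactly in floating point.  Ties in adjusted p are ordered
by term id for determinism.  The BiNGO-style color scale maps significant
adjusted p-values to [0, 1], linear in `−log10(p/α)` and saturating five
orders of magnitude below α; non-significant rows get a distinguished
`None`/`ns` code.

## Condensation

The link score is the **product-difference** form

    score(s → t) = v2(s)·v2(t) − v1(s)·v1(t)

applied identically to all three link types; `v_c(g)` is the mean of the
gene's replicate values in condition *c* after the chosen transform.  This
is the package's canonical "change along a link" statistic; it is isolated
behind the single `link_score` function so an alternative scoring rule can
be swapped in without touching ranking or retention.

Two preprocessing switches mirror common microarray practice:

* `transform`: `raw` or `log2` (log2 requires strictly positive
  intensities).
* `scoring_mode`: `plain`, or `variance_corrected`, which divides each
  gene's (transformed) values by the gene's pooled standard deviation over
  all samples of both conditions, floored at 1e-8.  The floor keeps the
  degenerate zero-variance case well-defined (v1 = v2, so such a gene's
  own change is zero), at the price that a perfectly constant gene is
  scaled to very large magnitude; real replicate data never has exactly
  zero pooled SD.  Probe-level rows mapping to one gene are collapsed by
  the per-sample mean before scoring.

Retention: each tail independently keeps `floor(fraction · n_scored)`
links (at least one when any link of that sign exists), ranked by |score|
with ties broken by canonical key — the two tails are phrased and bounded
separately ("top k% startups and top k% shutdowns").  Links with an
unmeasured endpoint are excluded, never imputed, and counted in
`n_unscored`.  Scores of exactly 0 are classed `unchanged` and never
retained.

Overlay colors are rank-based per condition: measured genes are ranked,
the median rank maps to 0 (white), the minimum to −1 (full green) and the
maximum to +1 (full red), piecewise-linearly in rank; this is monotone in
expression and robust to the intensity scale.  Unmeasured genes get NaN.

## Comparison

Node overlap is exact symbol matching; link overlap counts distinct
canonical keys shared under chosen identity options.  The default for
cross-network comparison ignores both type and direction — when two
networks use different type vocabularies, the unordered endpoint-pair
match is the only well-defined common denominator — with stricter modes
available.  Fractions are reported per network in full precision and as
rounded percents.  Reproducing a published intersection with an external
literature network additionally requires that network's edge list and its
curators' manual removal of indirect links; that comparison is therefore
out of scope here, and only the set-algebra semantics (self-identity,
symmetry, monotonicity under relaxed identity) are verified.

## Synthetic data

`simulate_network` draws exactly `n_links` distinct (pair, type,
direction) slots — at most 5 per unordered pair — with no self-loops,
uniform or preferential (degree + 1 weighted) endpoint sampling, and a
deterministic free-slot scan as fallback near capacity.  Defaults emulate
a curated pluripotency-scale network: **274 nodes, 574 links**,
40/40/20 interaction/stimulation/inhibition (the per-type composition of
such networks is not published; this mix was fixed once as a realistic
curated-network blend), preferential attachment so the degree distribution
is heavy-tailed like a literature-curated graph.  The synthetic graph is
*not* a replica of any curated network: its clustering coefficient is much
lower (pure preferential attachment creates few triangles) and its layout
of disconnected components differs, so topology tests validate the
statistics against brute-force oracles rather than against published
values.

`simulate_expression` emulates two-condition log-intensity microarray data:
per gene and replicate, `baseline_mean + N(0, noise_sd²)` (defaults 8 and
1, a typical log2 microarray scale), with the endpoint genes of planted
links shifted by `± effect_size · noise_sd` in condition 2 (up for
startups, down for shutdowns).  A gene touched by several same-direction
planted links shifts once; conflicting directions raise an error, and
`choose_planted` selects conflict-free planted sets.  Defaults — effect
size 3 SD, 3 replicates per condition — are the study conditions of the
recovery simulations.  What the generator does *not* emulate: probe
effects, batch effects, intensity-dependent variance, correlated
co-regulation beyond the planted shifts.  Passing recovery tests therefore
demonstrate the ranking machinery, not performance on real microarray
noise.

A note on recovery: a non-planted link whose two endpoints are both
dragged along by planted genes (common around hubs) scores as high as a
planted link.  At the default scale (574 links, 5% tails of 28, 10 planted)
this costs little — mean recovery ≈ 95–99% over 100 seeds — but in small
graphs where the tail size barely exceeds the planted count such bystander
links can displace planted ones; the simulation sizes used in the tests
and the acceptance script state this explicitly.

## Numerical and interface choices

* Hypergeometric tails via scipy's log-space survival function; exact 1.0
  at k = 0.  BH via statsmodels with the dominance clamp above.
* Dates are written `YYYY.MM.DD` and parsed leniently (also `-` and `/`
  separators); unparseable dates become empty, never fatal.
* Attribute-table column names are matched case-insensitively after
  stripping punctuation (`EntrezGene ID` ≡ `entrezgeneid`); edge keys use
  the classic `source (type) target` convention, and interaction keys
  match either endpoint order.
* XGMML input accepts bare documents and zip session containers (first
  member with a `<graph>` document wins); view properties are ignored.
  GraphML round-trips all curation attributes.
* CLI exit codes: 0 success, 2 usage/parameter error, 3 data/format error,
  4 computation error.  Logs go to stderr, data only to declared output
  files.  All randomized commands take `--seed`.

## Known limitations

* No GPML/WikiPathways or `.cys` session *writing*; no layout handling.
* Enrichment offers no hierarchy-aware (elim/weight) variants and no
  namespace bookkeeping beyond pass-through.
* The condensation score is one defensible formalization of "change along
  a link"; alternative link-score definitions (e.g. difference-based or
  correlation-based) are intentionally pluggable but not provided.
* Qualitative case-study claims on real reprogramming datasets (GEO
  accessions) require those downloads and are not part of the test suite;
  the planted-link simulations are the offline stand-in.
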