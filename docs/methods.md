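# Methods

## Data model

The store holds two document collections. A **taxon document** carries
an opaque taxon id, its rank, scientific name, all known names with
their name classes (scientific name, synonym, common name, …), and an
ordered lineage: the list of ancestors from the immediate parent to
the root, each with rank, name and depth (edges from the focal taxon,
parent = 1). An **assembly document** carries a primary accession, an
identifier list, the owning taxon and a copy of its lineage (self at
depth 0). Storing full lineages denormalises the tree so that "all
descendants of X" is a membership test rather than a traversal, which
is what makes clade-scoped search and reporting cheap.

Attribute semantics live in a registry keyed by attribute name: value
type (`integer`, `float`, `date`, `keyword`, `ordered_keyword`,
`list`), constraints (min/max bounds, an ordered enum for
ordered keywords, best label first), ordered summary rules, traversal
behaviour for fill, units and display metadata. Dates are held as ISO
`YYYY-MM-DD` strings throughout; with zero-padded fields their string
order is their calendar order, which keeps comparisons, summaries and
serialisation trivially consistent.

Per attribute, a document holds raw values (each with source name,
URL and import date), at most one summary, and at most one estimate
with provenance `direct`, `descendant` or `ancestor` — the green /
orange / red traffic-light classes surfaced by reports.

## Backbone loading and name resolution

The taxdump reader accepts the classic `\t|\t`-delimited dialect and a
plain-TSV fallback, consuming only the columns the model needs (node
id, parent, rank; name, name class). Structural defects — duplicate
ids, dangling parents, parent cycles, zero or multiple roots — are
hard errors naming the offender; a malformed backbone poisons
everything downstream, so there is no partial-load mode.

Off-backbone taxa are grafted under the most specific resolvable
anchor: anchors are given as rank → name pairs, tried from most to
least specific; an anchor name occurring at two taxa of the same rank
is ambiguous and rejected rather than guessed. Inserted taxa receive
negative-signed ids from a reserved namespace, assigned in input order
so reruns are stable, and are indexed under their scientific name
only.

Free-text lookup cascades through three tiers — case-insensitive exact
match on any name class, then prefix, then fuzzy within edit
distance 2 (computed with edlib) — returning the first non-empty tier.
Within a tier, shorter matched names sort first, then
lexicographically. Results always carry rank and parent name; the
engine never auto-picks among equal-tier homonyms.

## Import

Each source is a delimited table plus a YAML spec (schema in
`ingest.py`). Processing order per cell: translate (vocabulary
mapping) → transform (multiply/add constant, template join of columns,
case folding, date normalisation) → type coercion → constraint check.
Transforms run before constraints deliberately: a C-value of 1.0 pg is
valid only after conversion to 9.78 × 10⁸ bp (the standard
flow-cytometry conversion 1 pg = 0.978 × 10⁹ bp; the constant is
configurable in the YAML since it is a community convention, not a law
of nature).

Rows match to taxa through a fixed priority: explicit taxon id,
unique scientific name, name disambiguated by higher-rank columns,
synonym (if enabled), fuzzy (if enabled), insertion of a new taxon (if
enabled). Everything below the first two tiers is "inferred" and logged
to a review file. A bad cell voids only that cell — the partial-row
policy maximises retained data and matches the exceptions-file
framing — and every input row is accounted for: rows in = rows indexed
+ exception rows. Imports are idempotent on the key
(document, attribute, value, source name). Empty-cell markers default
to `"" NA None -` and are configurable. Delimiters come from the spec;
there is no sniffing, because declarative imports should not depend on
file content heuristics.

## Summaries and fill

`summarise` applies the first rule in the attribute's ordered rule
list that is applicable to the value type; min/max of the raw range
are recorded for numeric, date and ordered-keyword attributes (the
latter by enum position) and the count of raw values is kept. Mode
ties break by enum priority, then ascending value; medians of
even-length numeric lists are the mean of the central pair, while
non-averageable types (dates) take the lower-middle element.

Fill is deliberately simple — the backbone has no branch lengths, so
"nearest" means fewest edges:

* **UP pass** (directions `up`/`both`, post-order): a node without its
  own measurement receives the ancestor-summary statistic of its
  children's direct or descendant-derived values. Ancestor-derived
  values are never used as inputs, which prevents circular
  propagation. The statistic defaults to median for numeric and mode
  for categorical attributes, overridable per attribute.
* **DOWN pass** (directions `down`/`both`, pre-order): each node still
  lacking a value copies the value of its nearest ancestor that holds
  a direct or descendant-derived value, recording that ancestor as the
  source.

Direct summaries are never overwritten, and a node with raw values is
never re-derived from its children. Estimates are recomputed from
direct data on every run and compared against what is stored, so fill
is idempotent (a second pass writes zero changes) and incremental
changes touch only the affected root path and its descendants.

Barriers stop propagation in both directions. A **clade barrier**
blocks the named node and its entire subtree: nothing inside receives
an estimate and values inside never leak out (the canonical use:
organelle attributes measured in one kingdom must not be inferred for
another). A **rank barrier** blocks all nodes more inclusive than the
limit rank, cutting inheritance chains that would pass through them.
Both are expressed as `traverse.limit: {clade: NAME}` or
`{rank: LABEL}`.

List-typed attributes are not fillable: there is no defensible
ancestor-summary statistic for project-membership lists, so their
traverse direction must be `none`.

## Query language

A query is `term AND term AND …`. Taxon terms use `tax_`-prefixed
functions; attribute terms compare the reported value. The evaluator
computes a candidate id set per term (descendant sets by child
traversal, name hits via the name index, attribute comparisons over
slots) and intersects them; this indexed path is checked in the test
suite against an independent per-document linear-scan matcher on
~10⁴-document randomised stores.

Semantics worth stating explicitly:

* `tax_eq` matches ids; `tax_name` matches names (optionally
  restricted to a name class, `*`/`?` globbing allowed); `tax_tree`
  resolves its argument as an id first, then as a name, and matches
  the anchors plus all documents whose lineage contains them.
* `tax_lineage` requires a unique anchor and returns the anchor plus
  its ancestors — the full root path, self-inclusive, matching how a
  lineage is displayed.
* `tax_depth(n)` must co-occur with an anchoring taxon term and keeps
  documents within n edges below (or at) an anchor.
* Comma-joined values are OR; `!arg` and `!=` negate. `x != v` is the
  complement of `x = v` within the index, so documents lacking the
  attribute also match — the subtractive reading needed for
  "everything except" refinements.
* Ordering operators apply to numeric, date and ordered-keyword
  attributes only (enum position, best label greatest, so
  `assembly_level>=chromosome` admits `complete genome`); plain
  keywords support only `=`/`!=`. Keyword comparison is
  case-insensitive.
* `min()`/`max()` test the stored summary range (direct measurements
  only). `length()` counts distinct list members for list attributes —
  a single cell may carry several labels, and the question being asked
  is "how many projects list this taxon" — and raw rows otherwise.
* With estimates excluded, direct and descendant-derived values still
  satisfy attribute terms; only ancestor-derived values are hidden.
  The default includes estimates, since the flagship use (expected
  genome size for any species) depends on them.
* Results order by id (numeric ids numerically); general OR/NOT
  connectives are intentionally unsupported.

## Reports

All report totals reconcile with `count` of their source queries, and
binned reports never drop documents silently: documents without a
value are returned in an explicit `no_value` remainder (plus an
`unbinnable` count for non-positive values under log bins). Bins are
half-open and lower-inclusive; a value equal to the top edge clamps
into the last bin so totals conserve; log binning is base 10. Scatter
reports switch to a 2-D heatmap above a configurable threshold
(default 10,000 points). Tree reports build the minimal spanning
subtree of the matched taxa up to their most recent common ancestor,
annotate each node with matched-descendant counts and the attribute's
value and provenance class, and export as Newick (labels quoted when
they contain characters outside `[A-Za-z0-9_.|-]`, no branch lengths),
PhyloXML (annotations as property elements) or TSV.

## Synthetic fixtures

The generator emits a valid single-root taxonomy over the ranks
kingdom → species (bottom-up geometric partitioning, mean group sizes
~2–3 per level, so 1,000 species yield roughly 1,500 taxa), with
configurable homonym injection (species pairs in different families
sharing a name) and synonym rows. Attribute tables emulate the data
classes the engine targets: a log-normal genome-size trait (median
1.2 Gb, σ = 0.25 in log space, 70% missing), a Poisson
chromosome-number trait, an ordered sequencing-status keyword, and a
list-valued project target-list attribute. A configurable fraction of
families (default 15%) carries a large multiplicative shift (default
8×) on the numeric trait, far above the within-family noise, so
descendant estimates are statistically distinguishable; a ground-truth
table (every species' unmasked value and shift flag) accompanies each
masked table. Assembly tables draw spans and N50s log-normally with a
level correlated to scaffold N50.

What the fixtures do **not** emulate: real taxonomies' highly skewed
clade sizes and rank gaps ("no rank" chains), correlated missingness
(well-studied clades are measured more), inter-source disagreement
beyond independent noise, and name errors other than injected homonyms
and uniform misspellings. Passing tests therefore demonstrate
correctness of the mechanics (lineage indexing, matching tiers,
propagation, query semantics) and recoverability of strong clade
effects, not calibration on real data.

Fixture generation, and every stochastic test, is driven by explicit
integer seeds; identical seeds give byte-identical files.

## Problem sizes used in tests

The suite checks fill against a naive recursive oracle on 200 random
taxonomies of up to 200 nodes with 30% informative tips, across all
traverse directions and barrier settings; query semantics against a
per-document linear scan for 500 grammar-generated queries over a
store of ~10⁴ documents built through the full pipeline (5,000
species); Newick exports against an independent reader (dendropy) for
50 random subtrees; and clade-shift recovery on 1,500-species
fixtures, requiring ≥95% of shifted-clade genera on the correct side
of the global median. `scripts/acceptance.py` reruns the pipeline at
2,000 species.

## Known limitations

* Fill is nearest-neighbour copying and medians, not model-based
  ancestral reconstruction: no branch lengths, no uncertainty, no
  confidence intervals on estimates.
* One backbone at a time; merging or cross-indexing multiple
  taxonomies is out of scope.
* The store is a single in-process collection serialised to JSON;
  desk-scale (10⁵–10⁶ documents) is the design point, not a
  distributed corpus.
* `tax_rank` with no other taxon term scans the whole index; the CLI
  logs the potential cost but allows it.
* Date attributes support day granularity only, and date histograms
  are not implemented (convert to a numeric column upstream).
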