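# Methods

## Model

A query (contig or bin) is modelled as a collection of ORFs, each carrying
an independent taxonomic signal through its protein-database hits. Two
parameters control the classification:

* **r** — percent range below an ORF's top bit-score within which hits are
  included in that ORF's LCA. Unit: percent of the top bit-score, in
  [0, 100]. Defaults: 10 (contigs), 5 (bins). Small r keeps only near-top
  hits and yields specific per-ORF calls; large r pulls in divergent
  homologs, pushing the LCA rootward. The boundary is inclusive
  (*B* ≥ *B*_top × (1 − r/100)): a hit tied with the top hit must never be
  excluded.
* **f** — minimum fraction of the summed registered bit-score (*B*_sum)
  a taxon needs to be reported, in (0, 1]. Defaults: 0.5 (contigs), 0.3
  (bins). The threshold mbs = f × *B*_sum is compared inclusively. At
  f > 0.5 at most one lineage can qualify; below that, all deepest
  qualifying taxa are reported with their support fractions. Bins default
  to the lower f because their many ORFs make 30%-supported calls well
  backed in absolute evidence.

Per-ORF rules: hits whose accession has no taxid are dropped *before* the
top bit-score is determined — an unmappable hit carries no taxonomic
signal, so it should neither anchor nor inflate the range window.
Duplicate taxids collapse to a set before the LCA. Multiple HSPs of one
ORF–subject pair keep only the best-scoring line, so a single subject
cannot vote twice. ORFs with no hits, or none mappable, are reported with
a reason and contribute no weight to *B*_sum.

Voting and assignment: each classified ORF adds its registered (top-hit)
bit-score to every node on its LCA's lineage, so root support equals
*B*_sum by construction and support is non-increasing from root to leaf.
"Deepest qualifying" means a node qualifies only if no descendant on its
path also qualifies; qualifying siblings at *any* depth are all reported,
generalising multi-lineage reporting to lineages of unequal depth. Sibling
taxa tied at exactly the threshold are both reported; the majority
reduction (deepest node with support fraction strictly above 0.5, i.e. as
if f = 0.5) then stops at their parent — deterministic and conservative.

## Numerical choices

Bit-scores are decimals parsed from text and summed, so support
comparisons use a relative tolerance of 1e-9 to avoid boundary flapping;
the same tolerance makes the range boundary robust. Support fractions are
printed with four decimals, half-even rounding, and all writers use fixed
column orders and sort keys so outputs are byte-stable. Degenerate inputs
are values, not errors: empty hit groups, unmappable accessions and empty
vote tables flow through as "no hits"-style statuses. The classifier
itself is fully deterministic; only the synthetic generator consumes
seeds.

Taxonomy handling mirrors NCBI semantics: merged taxids are redirected
transitively before any lookup, deleted taxids resolve to a missing
marker, and names are presentation-only (unnamed nodes render as
`taxid:<n>`; classification never depends on names). Rank strings are
taken verbatim from `nodes.dmp`; only the seven official ranks
(superkingdom…species) are treated specially. The accession→taxid map
accepts the 4-column NCBI layout and a minimal 2-column one; an accession
listed with several taxids maps to their LCA (the first listed taxid need
not be the entry's LCA), and lines with unresolvable taxids are dropped
with a warning count rather than guessed at.

## Evaluation conventions

Contig-set scoring uses the lineage-subset rule: a prediction is correct
iff its whole lineage lies on the true lineage, so ancestors of the truth
are correct and anything deeper than the truth is not. Predictions at
unofficial ranks are projected to their deepest official ancestor before
scoring, and calls above superkingdom count as unclassified (trivially
informative). Rank integers run species = 0 … superkingdom = 6; in
per-rank breakdowns each rank is scored independently, so only the
too-specific part of a lineage is penalised. Sensitivity equals
fraction-classified × precision by construction.

Base-pair scoring evaluates one official rank at a time. Queries whose
truth lacks a node at that rank are excluded (no penalty for
over-specific predictions relative to the gold standard); real taxon bins
that attract no correct base pairs are included as zero-recall bins.
The small-bin filter removes predicted bins in ascending size order (ties
broken by taxon id, for determinism) while the removed total stays within
the threshold fraction (default 1%) of the predicted data.

## Synthetic generator

The generator emulates the inputs of the real pipeline — taxdump files,
a protein accession→taxid map, and outfmt-6 alignment tables — at toy
scale, with a known generative truth. Its defaults define the standing
test conditions: a balanced taxonomy with branching (2, 2, 2, 2, 3, 3, 3)
from superkingdom to species (432 species; three-way branching at the low
ranks so that after excluding a clade several equally near relatives
remain, whose LCA is their parent), 3 proteins per species, 8–12 ORFs per
contig, top-hit bit-scores Normal(300, 3), a linear bit-score decay of
15% per rank step of divergence, two sampled relatives per divergence
step up to three steps, and an off-target rate of 0.1 (one full-strength
hit to a uniformly random species, emulating conserved or horizontally
transferred genes). The 15% decay places same-genus hits at ~85% of the
top score — outside a 10% range window but inside 20% — which is the
regime the range parameter is designed to separate. Genome fragmentation
draws lognormal contig lengths (median 2 kb) truncated to a 300 nt
minimum and at most 65 fragments, a parametric stand-in for empirical
assembly length distributions.

What the generator does **not** emulate: real sequence evolution (scores
are drawn, not aligned), shared protein sequences across clades (every
accession belongs to one species, which makes clade exclusion by taxid
exact), unbalanced taxonomies, database annotation errors, and viral
taxonomy. Passing tests therefore demonstrate the algorithm's logic —
thresholding, voting, monotonicity, trend under unknownness — not
real-database performance figures.

Benchmark problem sizes are 50 queries per batch with per-query database
reductions, and 100–200 random cases per oracle comparison; these sizes
keep the whole suite and the acceptance script in the seconds-to-a-minute
range while giving stable fractions at the 2% granularity a 50-query
batch can resolve.

## Design notes

* The best-hit baseline (query takes its single top resolvable hit's
  taxon) lives in `taxvote.benchmark` as a named competitor, used by both
  the test suite and the acceptance script.
* Clade exclusion is implemented as a query-specific database reduction:
  every accession mapping into the query's ancestor at the excluded rank
  is removed, so each query faces a database in which its own clade was
  never sequenced.
* When a user supplies their own alignment table, the classifier cannot
  verify that hits down to r% of the top are present; a range parameter
  exceeding the declared table depth (default 50%) triggers a warning
  rather than silence.
* Whether the e-value cutoff is re-applied per hit or left to the aligner
  is an open convention; filtering happens once at parse time here.

## Known limitations

Support values are fractions of summed bit-score, not probabilities.
Bit-scores are taken as the aligner reports them; no re-scoring is
attempted. The tool classifies against whatever taxonomy it is given and
inherits its biases; byte-compatibility with other classifiers' output
formats is not claimed, only semantic equivalence of the content.
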