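"""Voting-based taxonomic classification of contigs and bins.

The algorithm has two stages. First each ORF is classified on its own: among
the hits whose subject accession resolves to a taxid, every hit with a
bit-score within ``r`` percent of the top hit's bit-score is kept, and the
ORF is assigned the last common ancestor (LCA) of the kept taxids; the
top-hit bit-score is registered as that ORF's vote weight. Second, the query
(a contig, or all contigs of a bin pooled) is classified by voting: each
classified ORF adds its registered bit-score to its LCA taxon and to every
ancestor up to the root. A taxon is supported when its summed bit-score
reaches the minimal bit-score support ``mbs = f × B_sum``, where ``B_sum``
is the total over classified ORFs; the query is assigned the deepest
supported taxa, each reported with its full lineage and per-node support
fractions.

Sequences with close relatives in the database are thereby classified at low
ranks, and divergent sequences — whose ORFs hit taxonomically scattered
subjects — automatically at higher ranks, without any fixed rank cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alignment import BinDefinition, OrfHitGroup, parse_orf_id
from .taxonomy import ProteinTaxonMap, TaxonomyTree

#: relative tolerance for support comparisons: bit-scores are sums of
#: decimals parsed from text, so exact boundary equality cannot be trusted
REL_EPS = 1e-9

REASON_NO_HITS = "no hits"
REASON_NO_TAXID = "no taxid for hits"

STATUS_CLASSIFIED = "classified"
STATUS_NO_HITS = "no ORFs with hits"


@dataclass(frozen=True)
class Params:
    """Classifier parameters.

    ``r`` is the percent range below the top bit-score within which hits are
    included in an ORF's LCA; ``f`` the minimum fraction of ``B_sum`` a
    taxon needs to be reported. Defaults are mode-specific: single contigs
    use r=10, f=0.5; bins use r=5, f=0.3, because the many ORFs of a bin
    back even low-``f`` calls with plenty of evidence.
    """

    r: float = 10.0
    f: float = 0.5
    evalue_cutoff: float = 0.001
    mode: str = "contig"

    def __post_init__(self) -> None:
        if not 0 <= self.r <= 100:
            raise ValueError("r must be a percentage in [0, 100]")
        if not 0 < self.f <= 1:
            raise ValueError("f must be a fraction in (0, 1]")

    @classmethod
    def contig_defaults(cls) -> "Params":
        return cls(r=10.0, f=0.5, mode="contig")

    @classmethod
    def bin_defaults(cls) -> "Params":
        return cls(r=5.0, f=0.3, mode="bin")


@dataclass
class OrfClassification:
    """One ORF's LCA assignment and registered (top-hit) bit-score."""

    orf_id: str
    contig_id: str
    lca_taxid: int | None
    registered_bitscore: float
    n_hits_in_range: int
    reason: str = ""

    @property
    def classified(self) -> bool:
        return self.lca_taxid is not None


@dataclass
class VoteTable:
    """Summed bit-score per taxon over a query's classified ORFs."""

    support_of: dict[int, float] = field(default_factory=dict)
    b_sum: float = 0.0


@dataclass
class QueryClassification:
    """Deepest supported lineage(s) of a contig or bin.

    ``lineages`` holds ``(lineage, fractions)`` pairs: the root-to-terminal
    taxid path and the parallel support fractions of ``B_sum``. Fractions
    are non-increasing along each lineage; each terminal's fraction is at
    least ``f``. At ``f > 0.5`` at most one lineage can qualify.
    """

    query_id: str
    lineages: list[tuple[tuple[int, ...], tuple[float, ...]]]
    n_orfs_total: int
    n_orfs_classified: int
    status: str
    b_sum: float = 0.0

    @property
    def classified(self) -> bool:
        return self.status == STATUS_CLASSIFIED


def classify_orf(
    group: OrfHitGroup,
    r: float,
    tree: TaxonomyTree,
    protmap: ProteinTaxonMap,
) -> OrfClassification:
    """Assign one ORF to the LCA of its top-range hits.

    Hits whose accession has no taxid are skipped before the top bit-score
    is determined; the range filter (inclusive: ``bitscore ≥ top ×
    (1 − r/100)``) then runs over the resolvable hits only. Failure modes
    are encoded in ``reason``, never raised.
    """
    contig_id, _ = parse_orf_id(group.orf_id)
    if not group.hits:
        return OrfClassification(group.orf_id, contig_id, None, 0.0, 0,
                                 reason=REASON_NO_HITS)
    resolved: list[tuple[float, int]] = []
    for hit in group.hits:
        taxid = protmap.get(hit.subject_accession)
        if taxid is None:
            continue
        taxid = tree.resolve(taxid)
        if taxid is None:
            continue
        resolved.append((hit.bitscore, taxid))
    if not resolved:
        return OrfClassification(group.orf_id, contig_id, None, 0.0, 0,
                                 reason=REASON_NO_TAXID)
    top = max(score for score, _ in resolved)
    threshold = top * (1.0 - r / 100.0)
    in_range = [(s, t) for s, t in resolved
                if s >= threshold * (1.0 - REL_EPS)]
    taxids = {t for _, t in in_range}
    return OrfClassification(
        orf_id=group.orf_id,
        contig_id=contig_id,
        lca_taxid=tree.lca(taxids),
        registered_bitscore=top,
        n_hits_in_range=len(in_range),
    )


def vote(orfs: Iterable[OrfClassification], tree: TaxonomyTree) -> VoteTable:
    """Sum registered bit-scores over taxa and all their ancestors.

    Every classified ORF adds its registered bit-score to each node on the
    lineage of its LCA taxon, root included, so ``support_of[root]`` equals
    ``b_sum`` by construction. Unclassified ORFs contribute nothing.
    """
    table = VoteTable()
    for orf in orfs:
        if not orf.classified:
            continue
        table.b_sum += orf.registered_bitscore
        for node in tree.lineage(orf.lca_taxid):
            table.support_of[node] = (
                table.support_of.get(node, 0.0) + orf.registered_bitscore
            )
    return table


def assign(
    query_id: str,
    votes: VoteTable,
    f: float,
    tree: TaxonomyTree,
    n_orfs_total: int = 0,
    n_orfs_classified: int = 0,
) -> QueryClassification:
    """Pick the deepest taxa whose support reaches ``mbs = f × B_sum``.

    A node is reported only when no node below it on the same path also
    qualifies; qualifying siblings at any depth are all reported (at
    ``f ≤ 0.5`` several lineages may pass the threshold). When nothing
    below the root qualifies the query is still reported with its trivial
    root lineage; downstream scoring decides informativeness.
    """
    if not 0 < f <= 1:
        raise ValueError("f must be a fraction in (0, 1]")
    if votes.b_sum <= 0:
        return QueryClassification(
            query_id=query_id, lineages=[], n_orfs_total=n_orfs_total,
            n_orfs_classified=n_orfs_classified, status=STATUS_NO_HITS,
        )
    mbs = f * votes.b_sum
    cutoff = mbs * (1.0 - REL_EPS)
    qualifying = {t for t, s in votes.support_of.items() if s >= cutoff}
    # terminal nodes: qualifying nodes with no qualifying strict descendant
    terminals = []
    for t in qualifying:
        lin = tree.lineage(t)
        if not any(u != t and t in tree.lineage(u) for u in qualifying):
            terminals.append((lin, t))
    terminals.sort(key=lambda e: e[0])  # deterministic output order
    lineages = []
    for lin, _ in terminals:
        fractions = tuple(votes.support_of[n] / votes.b_sum for n in lin)
        lineages.append((lin, fractions))
    return QueryClassification(
        query_id=query_id,
        lineages=lineages,
        n_orfs_total=n_orfs_total,
        n_orfs_classified=n_orfs_classified,
        status=STATUS_CLASSIFIED,
        b_sum=votes.b_sum,
    )


def classify_contig(
    contig_id: str,
    groups: Sequence[OrfHitGroup],
    params: Params,
    tree: TaxonomyTree,
    protmap: ProteinTaxonMap,
    n_orfs_total: int | None = None,
) -> tuple[QueryClassification, list[OrfClassification]]:
    """Classify one contig from its ORF hit groups.

    ``n_orfs_total`` may exceed ``len(groups)`` when hitless ORFs are known
    from the predicted-protein file. Returns the query classification and
    the per-ORF classifications (for the ORF-level output file).
    """
    orfs = [classify_orf(g, params.r, tree, protmap) for g in groups]
    votes = vote(orfs, tree)
    qc = assign(
        contig_id, votes, params.f, tree,
        n_orfs_total=n_orfs_total if n_orfs_total is not None else len(groups),
        n_orfs_classified=sum(o.classified for o in orfs),
    )
    return qc, orfs


def classify_bin(
    bin_def: BinDefinition,
    groups_per_contig: Mapping[str, Sequence[OrfHitGroup]],
    params: Params,
    tree: TaxonomyTree,
    protmap: ProteinTaxonMap,
    n_orfs_total: int | None = None,
) -> tuple[QueryClassification, list[OrfClassification]]:
    """Classify a bin by pooling ORF hit groups across all its contigs."""
    pooled: list[OrfHitGroup] = []
    for contig_id in sorted(bin_def.contig_ids):
        pooled.extend(groups_per_contig.get(contig_id, ()))
    qc, orfs = classify_contig(
        bin_def.bin_id, pooled, params, tree, protmap,
        n_orfs_total=n_orfs_total,
    )
    return qc, orfs


def reduce_to_majority(
    qc: QueryClassification, tree: TaxonomyTree
) -> QueryClassification:
    """Keep only the deepest node with a strict majority of the bit-score.

    Re-walks the reported lineages and keeps the deepest node with support
    fraction > 0.5, as if ``f = 0.5`` had been used: the conservative single
    classification used for scoring when ``f < 0.5`` produced several. Two
    siblings tied at exactly half each fail the strict majority, so the walk
    stops at their parent. Idempotent on majority-supported calls.
    """
    if not qc.classified or not qc.lineages:
        return qc
    best: tuple[int, ...] | None = None
    best_fracs: tuple[float, ...] | None = None
    for lin, fracs in qc.lineages:
        keep = 0
        for frac in fracs:
            if frac > 0.5 * (1.0 + REL_EPS):
                keep += 1
            else:
                break
        if best is None or keep > len(best):
            best = lin[:keep]
            best_fracs = fracs[:keep]
    assert best is not None and best_fracs is not None
    return QueryClassification(
        query_id=qc.query_id,
        lineages=[(best, best_fracs)],
        n_orfs_total=qc.n_orfs_total,
        n_orfs_classified=qc.n_orfs_classified,
        status=qc.status,
        b_sum=qc.b_sum,
    )
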