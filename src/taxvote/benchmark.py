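"""Clade-exclusion benchmarking of the voting classifier.

Drives the synthetic generator end to end: build a taxonomy and protein
database, draw a batch of query contigs, and classify each query against
databases with increasing unknownness — the full database, then databases
with the query's species, genus, or family excluded. The voting classifier
is compared with a conventional best-hit baseline (the query takes the
taxon of its single highest-scoring resolvable hit), the approach whose
spurious specificity on novel taxa motivates voting in the first place.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import alignment
from .classify import (
    Params,
    QueryClassification,
    STATUS_CLASSIFIED,
    STATUS_NO_HITS,
    classify_contig,
    reduce_to_majority,
)
from .evaluation import ContigSetScores, TruthAssignment, score_contig_set
from .synth import SynthConfig, SynthTaxonomy, clade_exclusion_reduce, \
    synth_query_batch, synth_taxonomy
from .taxonomy import ProteinTaxonMap, TaxonomyTree

EXCLUSION_LEVELS = ("none", "species", "genus", "family")


def best_hit_classify(
    contig_id: str,
    groups,
    tree: TaxonomyTree,
    protmap: ProteinTaxonMap,
) -> QueryClassification:
    """Best-hit baseline: the taxon of the single top resolvable hit."""
    best: tuple[float, int] | None = None
    for group in groups:
        for hit in group.hits:
            taxid = protmap.get(hit.subject_accession)
            taxid = tree.resolve(taxid) if taxid is not None else None
            if taxid is None:
                continue
            if best is None or hit.bitscore > best[0]:
                best = (hit.bitscore, taxid)
    if best is None:
        return QueryClassification(contig_id, [], len(groups), 0,
                                   STATUS_NO_HITS)
    lin = tree.lineage(best[1])
    return QueryClassification(
        contig_id, [(lin, tuple(1.0 for _ in lin))],
        len(groups), len(groups), STATUS_CLASSIFIED, b_sum=best[0],
    )


@dataclass
class CladeExclusionResult:
    """Scores for one classifier across the four exclusion levels."""

    scores: dict[str, ContigSetScores]
    mean_rank: dict[str, float | None]
    precision: dict[str, float]


@dataclass
class CladeExclusionBenchmark:
    world: SynthTaxonomy
    truth: TruthAssignment
    voting: CladeExclusionResult
    best_hit: CladeExclusionResult
    params: Params


def run_clade_exclusion(
    cfg: SynthConfig,
    n_queries: int = 50,
    params: Params | None = None,
) -> CladeExclusionBenchmark:
    """Run the full clade-exclusion experiment on one synthetic batch.

    Each query is classified four times, against the full protein database
    and against per-query reductions excluding its species, genus, and
    family. The database reduction is query-specific (excluding *that*
    query's clade), mirroring a benchmark in which every query represents
    a novel taxon at the stated rank.
    """
    params = params or Params.contig_defaults()
    world = synth_taxonomy(cfg)
    _, lines, truth = synth_query_batch(cfg, world, n_queries)
    hits = [
        alignment.AlignmentHit(
            orf_id=f[0],
            subject_accession=f[1],
            bitscore=float(f[11]),
            evalue=float(f[10]),
        )
        for f in (line.split("\t") for line in lines)
    ]
    grouped = alignment.group_hits(hits)

    reduced_cache: dict[tuple[str, int], ProteinTaxonMap] = {}

    def protmap_for(level: str, true_taxid: int) -> ProteinTaxonMap:
        if level == "none":
            return world.protmap
        key = (level, true_taxid)
        if key not in reduced_cache:
            reduced_cache[key] = clade_exclusion_reduce(
                world.protmap, world.tree, true_taxid, level
            )
        return reduced_cache[key]

    results = {}
    for name in ("voting", "best_hit"):
        scores: dict[str, ContigSetScores] = {}
        for level in EXCLUSION_LEVELS:
            predictions: dict[str, QueryClassification] = {}
            for contig_id, true_taxid in truth.taxid_of.items():
                groups = grouped.get(contig_id, [])
                protmap = protmap_for(level, true_taxid)
                if name == "voting":
                    qc, _ = classify_contig(
                        contig_id, groups, params, world.tree, protmap
                    )
                    qc = reduce_to_majority(qc, world.tree)
                else:
                    qc = best_hit_classify(
                        contig_id, groups, world.tree, protmap
                    )
                predictions[contig_id] = qc
            scores[level] = score_contig_set(predictions, truth, world.tree)
        results[name] = CladeExclusionResult(
            scores=scores,
            mean_rank={lv: s.mean_rank for lv, s in scores.items()},
            precision={lv: s.precision for lv, s in scores.items()},
        )
    return CladeExclusionBenchmark(
        world=world,
        truth=truth,
        voting=results["voting"],
        best_hit=results["best_hit"],
        params=params,
    )
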