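"""Synthetic taxonomies, protein databases, alignment tables, and benchmarks.

The generator emulates, at toy scale, everything the classifier consumes:
a full seven-rank taxonomy serialized in taxdump dialect, a protein
accession→taxid mapping, and per-query outfmt-6 alignment tables with a
controllable signal/noise structure. It also provides the two benchmark
constructions used to evaluate the classifier: fragmenting genomes into
contig sets, and clade exclusion — reducing the protein database so that
the query's species, genus, or family looks like it was never sequenced.

Bit-score model: each ORF's hit to a protein of its own species scores
``Normal(mean, sd)``; a hit to a species whose divergence from the truth is
``d`` rank steps (1 = same genus, 2 = same family, …) scores
``Normal(mean × (1 − decay × d), sd)``. Linear decay is a modelling choice:
it only needs to create a controllable ladder of signal so that range and
support thresholds can be exercised, not to mimic any real aligner.
Off-target hits (conserved or horizontally transferred genes that align
best to a distant clade) are injected per ORF at a configurable rate, with
full-strength bit-scores against a uniformly random species.

Every artifact is a pure function of ``(config, seed)``: identical inputs
give byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .taxonomy import (
    OFFICIAL_RANKS,
    ProteinTaxonMap,
    TaxonomyTree,
    write_accession2taxid,
    write_taxdump,
)
from .evaluation import TruthAssignment


@dataclass
class SynthConfig:
    """Configuration of the synthetic world.

    ``children_per_rank`` gives the branching factor at each of the seven
    official ranks, superkingdom first. ``decay_per_step`` is the relative
    bit-score lost per rank step of divergence; with the defaults a
    same-genus hit scores ~85% of a same-species hit, which falls outside a
    10% range window but inside a 20% one — the regime the range parameter
    is designed to separate.
    """

    seed: int = 0
    children_per_rank: tuple[int, ...] = (2, 2, 2, 2, 3, 3, 3)
    proteins_per_species: int = 3
    orfs_per_contig: tuple[int, int] = (8, 12)
    bitscore_mean: float = 300.0
    bitscore_sd: float = 3.0
    decay_per_step: float = 0.15
    off_target_rate: float = 0.1
    relatives_per_step: int = 2
    divergence_steps: int = 3
    strain_nodes: bool = False

    def __post_init__(self) -> None:
        if len(self.children_per_rank) != len(OFFICIAL_RANKS):
            raise ValueError("children_per_rank needs 7 entries")
        if any(c < 1 for c in self.children_per_rank):
            raise ValueError("all branching factors must be ≥ 1")
        if not 0 <= self.off_target_rate <= 1:
            raise ValueError("off_target_rate must be in [0, 1]")


@dataclass
class SynthTaxonomy:
    """A generated taxonomy plus its protein database."""

    tree: TaxonomyTree
    protmap: ProteinTaxonMap
    species: list[int]
    accessions_of: dict[int, list[str]] = field(default_factory=dict)


def synth_taxonomy(cfg: SynthConfig) -> SynthTaxonomy:
    """Build a full seven-rank taxonomy with proteins for every species.

    Node taxids are assigned breadth-first from 2 (root is 1); names encode
    rank and position (e.g. ``genus_17``). With ``strain_nodes`` each
    species receives one "no rank" child, exercising below-species lineage
    handling. Each species gets ``proteins_per_species`` accessions
    ``P<taxid>.<i>``.
    """
    parent_of = {1: 1}
    rank_of = {1: "no rank"}
    name_of = {1: "root"}
    next_id = 2
    frontier = [1]
    species: list[int] = []
    for rank, n_children in zip(OFFICIAL_RANKS, cfg.children_per_rank):
        new_frontier = []
        for parent in frontier:
            for _ in range(n_children):
                taxid = next_id
                next_id += 1
                parent_of[taxid] = parent
                rank_of[taxid] = rank
                name_of[taxid] = f"{rank}_{taxid}"
                new_frontier.append(taxid)
                if rank == "species":
                    species.append(taxid)
        frontier = new_frontier
    if cfg.strain_nodes:
        for sp in list(species):
            taxid = next_id
            next_id += 1
            parent_of[taxid] = sp
            rank_of[taxid] = "no rank"
            name_of[taxid] = f"strain_{taxid}"
    tree = TaxonomyTree(parent_of=parent_of, rank_of=rank_of,
                        name_of=name_of, root_id=1)
    accessions_of = {
        sp: [f"P{sp}.{i + 1}" for i in range(cfg.proteins_per_species)]
        for sp in species
    }
    taxid_of = {
        acc: sp for sp, accs in accessions_of.items() for acc in accs
    }
    return SynthTaxonomy(
        tree=tree,
        protmap=ProteinTaxonMap(taxid_of=taxid_of),
        species=species,
        accessions_of=accessions_of,
    )


def write_synth_database(world: SynthTaxonomy, directory) -> dict[str, str]:
    """Serialize the synthetic taxonomy and protein map to disk.

    Emits the same dialects the real pipeline consumes (taxdump files and a
    prot.accession2taxid TSV) so fixtures exercise every parser. Returns
    the paths written.
    """
    os.makedirs(directory, exist_ok=True)
    write_taxdump(world.tree, directory)
    acc_path = os.path.join(directory, "prot.accession2taxid")
    write_accession2taxid(world.protmap.taxid_of, acc_path)
    return {
        "nodes": os.path.join(directory, "nodes.dmp"),
        "names": os.path.join(directory, "names.dmp"),
        "accession2taxid": acc_path,
    }


def _divergence_pools(
    world: SynthTaxonomy, true_species: int, max_steps: int
) -> list[list[int]]:
    """Species grouped by rank-step divergence from the true species.

    Divergence ``d`` means the LCA with the truth sits ``d`` rank steps
    above the species rank (1 = same genus, 2 = same family, …).
    """
    tree = world.tree
    lineage = tree.lineage(true_species)
    pools: list[list[int]] = []
    inner = {true_species}
    for d in range(1, max_steps + 1):
        ancestor = lineage[-(d + 1)]
        members = [
            sp for sp in world.species
            if sp not in inner and ancestor in tree.lineage(sp)
        ]
        pools.append(sorted(members))
        inner.update(members)
    return pools


def synth_query(
    cfg: SynthConfig,
    true_species: int,
    world: SynthTaxonomy,
    rng: np.random.Generator,
    contig_id: str = "contig_1",
    n_orfs: int | None = None,
) -> tuple[list[str], list[str], TruthAssignment]:
    """Generate one query contig's protein headers and alignment lines.

    Each ORF receives a top hit to a protein of the true species, hits to
    ``relatives_per_step`` species at each divergence step (bit-scores
    decayed per step), and — at the off-target rate — one full-strength hit
    to a uniformly random species. Returns (protein FASTA header ids,
    outfmt-6 lines, truth).
    """
    if n_orfs is None:
        lo, hi = cfg.orfs_per_contig
        n_orfs = int(rng.integers(lo, hi + 1))
    pools = _divergence_pools(world, true_species, cfg.divergence_steps)
    orf_ids: list[str] = []
    lines: list[str] = []

    def emit(orf_id: str, species: int, score: float) -> None:
        accs = world.accessions_of[species]
        acc = accs[int(rng.integers(0, len(accs)))]
        score = max(25.0, score)
        lines.append(
            f"{orf_id}\t{acc}\t95.0\t200\t10\t0\t1\t200\t1\t200\t"
            f"1e-50\t{score:.1f}"
        )

    for i in range(1, n_orfs + 1):
        orf_id = f"{contig_id}_{i}"
        orf_ids.append(orf_id)
        emit(orf_id, true_species,
             rng.normal(cfg.bitscore_mean, cfg.bitscore_sd))
        for d, pool in enumerate(pools, start=1):
            if not pool:
                continue
            k = min(cfg.relatives_per_step, len(pool))
            chosen = rng.choice(len(pool), size=k, replace=False)
            level_mean = cfg.bitscore_mean * (1 - cfg.decay_per_step * d)
            for j in sorted(chosen):
                emit(orf_id, pool[j],
                     rng.normal(level_mean, cfg.bitscore_sd))
        if rng.random() < cfg.off_target_rate:
            other = world.species[int(rng.integers(0, len(world.species)))]
            emit(orf_id, other,
                 rng.normal(cfg.bitscore_mean, cfg.bitscore_sd))
    truth = TruthAssignment(taxid_of={contig_id: true_species})
    return orf_ids, lines, truth


def synth_query_batch(
    cfg: SynthConfig,
    world: SynthTaxonomy,
    n_queries: int,
    seed: int | None = None,
) -> tuple[dict[str, list[str]], list[str], TruthAssignment]:
    """Generate a batch of query contigs with distinct true species.

    Species are sampled without replacement when possible. Returns
    (orf ids per contig, pooled alignment lines, truth with synthetic
    contig lengths).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    replace = n_queries > len(world.species)
    chosen = rng.choice(len(world.species), size=n_queries, replace=replace)
    orf_ids: dict[str, list[str]] = {}
    lines: list[str] = []
    taxid_of: dict[str, int] = {}
    length_of: dict[str, int] = {}
    for q, idx in enumerate(chosen, start=1):
        contig_id = f"contig_{q}"
        sp = world.species[int(idx)]
        ids, contig_lines, _ = synth_query(
            cfg, sp, world, rng, contig_id=contig_id
        )
        orf_ids[contig_id] = ids
        lines.extend(contig_lines)
        taxid_of[contig_id] = sp
        length_of[contig_id] = int(rng.lognormal(np.log(2000), 0.5))
    return orf_ids, lines, TruthAssignment(taxid_of, length_of)


def fragment_genome(
    sequence: str,
    rng: np.random.Generator,
    min_len: int = 300,
    max_fragments: int = 65,
    mean_log_len: float = np.log(2000),
    sd_log_len: float = 1.0,
) -> list[tuple[int, int, str]]:
    """Cut a genome into at most ``max_fragments`` non-overlapping contigs.

    Fragment lengths are drawn from a lognormal distribution (a stand-in
    for empirical assembly length distributions), truncated to
    ``[min_len, remaining]``; fragments are laid left to right so they can
    never overlap, and trailing sequence shorter than ``min_len`` is left
    uncovered. Returns (start, end, subsequence) triples.
    """
    if len(sequence) < min_len:
        raise ValueError(
            f"sequence of length {len(sequence)} is shorter than the "
            f"minimum contig length {min_len}"
        )
    fragments: list[tuple[int, int, str]] = []
    pos = 0
    while len(fragments) < max_fragments and len(sequence) - pos >= min_len:
        remaining = len(sequence) - pos
        length = int(round(rng.lognormal(mean_log_len, sd_log_len)))
        length = max(min_len, min(length, remaining))
        fragments.append((pos, pos + length, sequence[pos:pos + length]))
        pos += length
    return fragments


def clade_exclusion_reduce(
    protmap: ProteinTaxonMap,
    tree: TaxonomyTree,
    query_taxid: int,
    level: str,
) -> ProteinTaxonMap:
    """Remove all proteins confined to the query's species/genus/family.

    Simulates a reference database in which the query's clade at ``level``
    was never sequenced: every accession whose taxid falls inside the
    query's ancestor at that rank is dropped. Proteins shared with outside
    clades are modelled as separate accessions here, so dropping by taxid
    is exact.
    """
    if level not in ("species", "genus", "family"):
        raise ValueError("level must be species, genus or family")
    clade = tree.official_rank_projection(query_taxid).get(level)
    if clade is None:
        raise ValueError(
            f"taxid {query_taxid} has no ancestor at rank {level!r}"
        )
    kept = {
        acc: taxid for acc, taxid in protmap.taxid_of.items()
        if clade not in tree.lineage(taxid)
    }
    return ProteinTaxonMap(taxid_of=kept)
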