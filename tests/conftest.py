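"""Shared fixtures: a small hand-built taxonomy and a seeded synthetic world."""

import numpy as np
import pytest

from taxvote.alignment import AlignmentHit, OrfHitGroup
from taxvote.synth import SynthConfig, synth_taxonomy
from taxvote.taxonomy import ProteinTaxonMap, TaxonomyTree


@pytest.fixture
def hand_tree() -> TaxonomyTree:
    """A tiny, fully enumerable taxonomy.

    root(1) → superkingdom 2 → phylum 10 → class 20 → order 30
    → families 40, 41; genus 50 (in 40) with species 60, 61;
    genus 51 (in 41) with species 70; "no rank" strain 600 under 60.
    """
    parent_of = {
        1: 1, 2: 1, 10: 2, 20: 10, 30: 20,
        40: 30, 41: 30, 50: 40, 51: 41,
        60: 50, 61: 50, 70: 51, 600: 60,
    }
    rank_of = {
        1: "no rank", 2: "superkingdom", 10: "phylum", 20: "class",
        30: "order", 40: "family", 41: "family", 50: "genus",
        51: "genus", 60: "species", 61: "species", 70: "species",
        600: "no rank",
    }
    name_of = {1: "root", 2: "sk", 50: "genus fifty", 60: "species sixty"}
    return TaxonomyTree(parent_of=parent_of, rank_of=rank_of,
                        name_of=name_of, root_id=1)


@pytest.fixture
def hand_protmap() -> ProteinTaxonMap:
    return ProteinTaxonMap(taxid_of={
        "P60": 60, "P61": 61, "P70": 70, "P50": 50, "P600": 600,
    })


def make_group(orf_id: str, scored_hits) -> OrfHitGroup:
    """Build a hit group from (accession, bitscore) pairs, sorted."""
    hits = [
        AlignmentHit(orf_id=orf_id, subject_accession=acc,
                     bitscore=float(score), evalue=1e-20)
        for acc, score in scored_hits
    ]
    hits.sort(key=lambda h: -h.bitscore)
    from taxvote.alignment import parse_orf_id
    contig_id, _ = parse_orf_id(orf_id)
    return OrfHitGroup(orf_id=orf_id, contig_id=contig_id, hits=hits)


@pytest.fixture(scope="session")
def small_world():
    """Seeded synthetic world: 128 species, strain nodes included."""
    cfg = SynthConfig(seed=7, children_per_rank=(2, 2, 2, 2, 2, 2, 2),
                      strain_nodes=True)
    return synth_taxonomy(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
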