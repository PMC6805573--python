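"""Benchmark scoring: contig-set measures and base-pair (bin purity) measures.

Two complementary frameworks:

* **Contig-set scoring** treats every query equally. A prediction is
  *correct* when its lineage is a subset of the true lineage — a call at
  genus rank for a species-level truth is correct, a call deeper than the
  truth (spurious specificity) is not. Reported measures: fraction of
  classified queries, precision (correct / classified), sensitivity
  (correct / total, which equals fraction_classified × precision), and the
  mean/median taxonomic rank of classification on an integer scale
  (species = 0 … superkingdom = 6). Queries classified above superkingdom
  ("root", "cellular organisms") are trivially informative and counted as
  unclassified.

* **Base-pair scoring** weights by sequence length and evaluates one
  official rank at a time, as in community-challenge taxonomic binning:
  accuracy and misclassification are properties of the whole assembly,
  while average precision is the mean purity of predicted taxon bins and
  average recall the mean completeness of real taxon bins. Because a few
  misclassified small bins dominate average precision, a variant excludes
  the smallest predicted bins summing up to 1% of the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, median
from typing import Mapping

from .classify import QueryClassification
from .taxonomy import OFFICIAL_RANKS, TaxonomyTree

#: species = 0 … superkingdom = 6
RANK_INTS = {rank: i for i, rank in enumerate(reversed(OFFICIAL_RANKS))}


@dataclass
class TruthAssignment:
    """Ground truth: query → true taxid, optionally query → length (bp)."""

    taxid_of: dict[str, int]
    length_of: dict[str, int] | None = None


@dataclass
class RankScores:
    fraction_classified: float
    precision: float
    sensitivity: float


@dataclass
class ContigSetScores:
    fraction_classified: float
    sensitivity: float
    precision: float
    mean_rank: float | None
    median_rank: float | None
    n_queries: int
    per_rank: dict[str, RankScores]


@dataclass
class CamiScores:
    rank: str
    accuracy: float
    misclassification: float
    average_precision: float
    average_recall: float
    n_predicted_bins: int
    n_real_bins: int


def rank_to_int(rank_name: str) -> int:
    """Integer value of an official rank: species=0 … superkingdom=6."""
    try:
        return RANK_INTS[rank_name]
    except KeyError:
        raise ValueError(f"{rank_name!r} is not an official rank") from None


def is_correct(
    predicted_lineage,
    true_taxid: int,
    tree: TaxonomyTree,
) -> bool:
    """Lineage-subset correctness rule.

    True iff every node of the predicted lineage lies on the true taxon's
    lineage; a prediction deeper than the truth is incorrect (classified
    too specifically).
    """
    true_lineage = set(tree.lineage(true_taxid))
    return all(node in true_lineage for node in predicted_lineage)


def _projected_terminal(
    qc: QueryClassification, tree: TaxonomyTree
) -> tuple[str, int] | None:
    """Deepest official (rank, node) of a prediction, or None.

    Predictions at unofficial ranks are projected to their deepest official
    ancestor; a prediction that never reaches superkingdom projects to
    nothing and counts as unclassified.
    """
    if not qc.classified or not qc.lineages:
        return None
    lin, _ = qc.lineages[0]
    return tree.deepest_official(lin[-1])


def score_contig_set(
    predictions: Mapping[str, QueryClassification],
    truth: TruthAssignment,
    tree: TaxonomyTree,
) -> ContigSetScores:
    """Score a set of classified queries against per-query truth.

    ``predictions`` should be majority-reduced when produced with
    ``f < 0.5`` so each query carries a single lineage. Every predicted
    query must be present in the truth.
    """
    missing = set(predictions) - set(truth.taxid_of)
    if missing:
        raise KeyError(
            "queries absent from truth: " + ", ".join(sorted(missing))
        )
    n = len(truth.taxid_of)
    n_classified = 0
    n_correct = 0
    ranks: list[int] = []
    # per-rank tallies: each rank scored independently against the truth
    per_rank_cls = {r: 0 for r in OFFICIAL_RANKS}
    per_rank_cor = {r: 0 for r in OFFICIAL_RANKS}
    for query_id, true_taxid in truth.taxid_of.items():
        qc = predictions.get(query_id)
        terminal = _projected_terminal(qc, tree) if qc is not None else None
        if terminal is None:
            continue
        rank, node = terminal
        n_classified += 1
        ranks.append(rank_to_int(rank))
        if is_correct(tree.lineage(node), true_taxid, tree):
            n_correct += 1
        truth_proj = tree.official_rank_projection(true_taxid)
        pred_proj = tree.official_rank_projection(node)
        for r, pred_node in pred_proj.items():
            per_rank_cls[r] += 1
            if truth_proj.get(r) == pred_node:
                per_rank_cor[r] += 1
    per_rank = {
        r: RankScores(
            fraction_classified=per_rank_cls[r] / n if n else 0.0,
            precision=(per_rank_cor[r] / per_rank_cls[r]
                       if per_rank_cls[r] else 0.0),
            sensitivity=per_rank_cor[r] / n if n else 0.0,
        )
        for r in OFFICIAL_RANKS
    }
    return ContigSetScores(
        fraction_classified=n_classified / n if n else 0.0,
        sensitivity=n_correct / n if n else 0.0,
        precision=n_correct / n_classified if n_classified else 0.0,
        mean_rank=mean(ranks) if ranks else None,
        median_rank=median(ranks) if ranks else None,
        n_queries=n,
        per_rank=per_rank,
    )


def _predictions_at_rank(
    predictions: Mapping[str, QueryClassification],
    tree: TaxonomyTree,
    rank: str,
) -> dict[str, int]:
    """Query → predicted node at ``rank`` (queries predicted above it drop)."""
    out: dict[str, int] = {}
    for query_id, qc in predictions.items():
        terminal = _projected_terminal(qc, tree)
        if terminal is None:
            continue
        node = tree.official_rank_projection(terminal[1]).get(rank)
        if node is not None:
            out[query_id] = node
    return out


def cami_score(
    predictions: Mapping[str, QueryClassification],
    truth: TruthAssignment,
    tree: TaxonomyTree,
    rank: str,
) -> CamiScores:
    """Base-pair measures at one official rank.

    Accuracy = correctly classified bp / total bp; misclassification =
    incorrectly classified bp / total bp (unassigned bp count in neither
    numerator). Average precision is the mean purity over predicted taxon
    bins, average recall the mean completeness over real taxon bins; real
    bins with no correct base pairs count as zero recall. Queries whose
    truth lacks a node at ``rank`` are not taken into account, so there is
    no penalty for predictions more specific than the gold standard.
    """
    if rank not in OFFICIAL_RANKS:
        raise ValueError(f"{rank!r} is not an official rank")
    if truth.length_of is None:
        raise ValueError("base-pair scoring requires query lengths")
    missing = set(truth.taxid_of) - set(truth.length_of)
    if missing:
        raise ValueError(
            "queries without lengths: " + ", ".join(sorted(missing))
        )
    predicted_at = _predictions_at_rank(predictions, tree, rank)
    total_bp = 0
    correct_bp = 0
    wrong_bp = 0
    pred_bins: dict[int, list[tuple[int, bool]]] = {}
    real_bins: dict[int, list[tuple[int, bool]]] = {}
    for query_id, true_taxid in truth.taxid_of.items():
        true_node = tree.official_rank_projection(true_taxid).get(rank)
        if true_node is None:
            continue  # rank not present in the gold standard for this query
        length = truth.length_of[query_id]
        total_bp += length
        pred_node = predicted_at.get(query_id)
        correct = pred_node == true_node
        if pred_node is not None:
            if correct:
                correct_bp += length
            else:
                wrong_bp += length
            pred_bins.setdefault(pred_node, []).append((length, correct))
        real_bins.setdefault(true_node, []).append((length, correct))
    precisions = [
        sum(l for l, ok in entries if ok) / sum(l for l, _ in entries)
        for entries in pred_bins.values()
    ]
    recalls = [
        sum(l for l, ok in entries if ok) / sum(l for l, _ in entries)
        for entries in real_bins.values()
    ]
    return CamiScores(
        rank=rank,
        accuracy=correct_bp / total_bp if total_bp else 0.0,
        misclassification=wrong_bp / total_bp if total_bp else 0.0,
        average_precision=mean(precisions) if precisions else 0.0,
        average_recall=mean(recalls) if recalls else 0.0,
        n_predicted_bins=len(pred_bins),
        n_real_bins=len(real_bins),
    )


def filter_small_bins(
    predictions: Mapping[str, QueryClassification],
    truth: TruthAssignment,
    tree: TaxonomyTree,
    rank: str,
    threshold_fraction: float = 0.01,
) -> dict[str, QueryClassification]:
    """Drop queries in the smallest predicted bins, up to a data fraction.

    Predicted bins at ``rank`` are removed in ascending total-length order
    (ties broken by taxon id) while the cumulative removed length stays
    ≤ ``threshold_fraction`` of the total predicted length. The surviving
    predictions are returned for re-scoring; average precision recomputed
    on them is insensitive to tiny impure bins.
    """
    if not 0 <= threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in [0, 1)")
    if truth.length_of is None:
        raise ValueError("bin filtering requires query lengths")
    predicted_at = _predictions_at_rank(predictions, tree, rank)
    bin_members: dict[int, list[str]] = {}
    for query_id, node in predicted_at.items():
        bin_members.setdefault(node, []).append(query_id)
    sizes = {
        node: sum(truth.length_of[q] for q in members)
        for node, members in bin_members.items()
    }
    total = sum(sizes.values())
    budget = threshold_fraction * total
    removed_queries: set[str] = set()
    removed = 0
    for node in sorted(sizes, key=lambda t: (sizes[t], t)):
        if removed + sizes[node] > budget:
            break
        removed += sizes[node]
        removed_queries.update(bin_members[node])
    return {
        q: qc for q, qc in predictions.items() if q not in removed_queries
    }
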