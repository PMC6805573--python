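"""Classification output files, taxon naming, and result summaries.

All writers are deterministic: fixed column order, fixed sort keys, and
support fractions printed with four decimals (half-even rounding), so
identical inputs produce byte-identical files.

File layouts (frozen here, exercised by golden-file tests):

``orf2lca`` — one line per ORF::

    # orf_id  contig_id  classification  bitscore  n_hits_in_range

where ``classification`` is the LCA taxid, or a reason token for
unclassified ORFs (then ``bitscore`` and ``n_hits_in_range`` are ``NA``).

``classification`` — one line per reported lineage::

    # query_id  status  n_orfs_total  n_orfs_classified  lineage  support

``lineage`` is the semicolon-joined root-to-terminal taxid path and
``support`` the parallel semicolon-joined fractions; unclassified queries
produce exactly one line with ``NA`` paths.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .alignment import parse_orf_id
from .classify import (
    OrfClassification,
    QueryClassification,
    STATUS_CLASSIFIED,
)
from .taxonomy import OFFICIAL_RANKS, TaxonomyTree

NA = "NA"
NOT_CLASSIFIED = "not classified"

ORF2LCA_HEADER = "# orf_id\tcontig_id\tclassification\tbitscore\tn_hits_in_range"
CLASSIFICATION_HEADER = (
    "# query_id\tstatus\tn_orfs_total\tn_orfs_classified\tlineage\tsupport"
)


def _fmt_fraction(x: float) -> str:
    # Python's round is half-even, which keeps golden files stable
    return f"{round(x, 4):.4f}"


def write_orf2lca(orfs: Iterable[OrfClassification], path) -> None:
    """Write the per-ORF output file, ordered by (contig, ORF index)."""
    rows = sorted(orfs, key=lambda o: (o.contig_id, parse_orf_id(o.orf_id)[1]))
    with open(path, "w") as fh:
        fh.write(ORF2LCA_HEADER + "\n")
        for o in rows:
            if o.classified:
                fh.write(
                    f"{o.orf_id}\t{o.contig_id}\t{o.lca_taxid}\t"
                    f"{o.registered_bitscore:.1f}\t{o.n_hits_in_range}\n"
                )
            else:
                fh.write(f"{o.orf_id}\t{o.contig_id}\t{o.reason}\t{NA}\t{NA}\n")


def read_orf2lca(path) -> list[OrfClassification]:
    """Re-parse an ``orf2lca`` file back into ORF classifications."""
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.rstrip("\n") != ORF2LCA_HEADER:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for raw in fh:
            orf_id, contig_id, cls, bitscore, n_range = (
                raw.rstrip("\n").split("\t")
            )
            if bitscore == NA:
                out.append(OrfClassification(orf_id, contig_id, None, 0.0, 0,
                                             reason=cls))
            else:
                out.append(OrfClassification(orf_id, contig_id, int(cls),
                                             float(bitscore), int(n_range)))
    return out


def write_classification(
    records: Iterable[QueryClassification], path
) -> None:
    """Write the query-level output file, one line per reported lineage."""
    with open(path, "w") as fh:
        fh.write(CLASSIFICATION_HEADER + "\n")
        for qc in sorted(records, key=lambda q: q.query_id):
            base = (
                f"{qc.query_id}\t{qc.status}\t{qc.n_orfs_total}\t"
                f"{qc.n_orfs_classified}"
            )
            if not qc.classified or not qc.lineages:
                fh.write(f"{base}\t{NA}\t{NA}\n")
                continue
            for lin, fracs in qc.lineages:
                path_s = ";".join(str(t) for t in lin)
                supp_s = ";".join(_fmt_fraction(x) for x in fracs)
                fh.write(f"{base}\t{path_s}\t{supp_s}\n")


def add_names(
    in_path,
    out_path,
    tree: TaxonomyTree,
    only_official: bool = False,
    strict: bool = False,
) -> None:
    """Append taxon-name columns to a classification or orf2lca file.

    In full-lineage mode one column is appended holding a semicolon-joined
    list of ``name (rank)`` entries, one per taxid in the path. With
    ``only_official`` the lineage is instead projected onto the seven
    official ranks, one column per rank (superkingdom → species), with
    ``not classified`` placeholders for ranks the lineage does not reach.
    Taxids absent from the tree render as ``unknown taxid`` unless
    ``strict``, in which case they raise.
    """
    with open(in_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header == ORF2LCA_HEADER:
            taxid_col, is_path = 2, False
        elif header == CLASSIFICATION_HEADER:
            taxid_col, is_path = 4, True
        else:
            raise ValueError(f"{in_path}: unrecognised header {header!r}")
        lines = [raw.rstrip("\n") for raw in fh]

    if only_official:
        extra_header = "\t".join(OFFICIAL_RANKS)
    else:
        extra_header = "lineage_names"

    with open(out_path, "w") as out:
        out.write(header + "\t" + extra_header + "\n")
        for line in lines:
            fields = line.split("\t")
            token = fields[taxid_col]
            taxids = _parse_path(token, is_path)
            if taxids is None:
                filler = (
                    [NOT_CLASSIFIED] * len(OFFICIAL_RANKS)
                    if only_official else [NA]
                )
                out.write(line + "\t" + "\t".join(filler) + "\n")
                continue
            out.write(line + "\t" + _name_columns(
                taxids, tree, only_official, strict) + "\n")


def _parse_path(token: str, is_path: bool) -> list[int] | None:
    if token == NA:
        return None
    if is_path:
        parts = token.split(";")
    else:
        parts = [token]
    try:
        return [int(p) for p in parts]
    except ValueError:
        return None  # reason token on an unclassified ORF line


def _name_columns(
    taxids: Sequence[int],
    tree: TaxonomyTree,
    only_official: bool,
    strict: bool,
) -> str:
    def label(t: int) -> str:
        if t not in tree:
            if strict:
                raise KeyError(f"taxid {t} absent from taxonomy")
            return "unknown taxid"
        return f"{tree.name(t)} ({tree.rank_of.get(t, 'no rank')})"

    if not only_official:
        return ";".join(label(t) for t in taxids)
    terminal = taxids[-1]
    if terminal in tree:
        projection = tree.official_rank_projection(terminal)
    else:
        if strict:
            raise KeyError(f"taxid {terminal} absent from taxonomy")
        projection = {}
    cols = []
    for rank in OFFICIAL_RANKS:
        node = projection.get(rank)
        cols.append(label(node) if node is not None else NOT_CLASSIFIED)
    return "\t".join(cols)


def contig_lengths_from_fasta(path) -> dict[str, int]:
    """Contig id → length in bp, from a FASTA file."""
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def summarise(
    named_path,
    out_path,
    mode: str = "contig",
    contig_lengths: Mapping[str, int] | None = None,
) -> dict[str, dict[str, float]]:
    """Summarise an official-rank named classification file.

    In contig mode, reports the total length of the contigs classified to
    each taxon per official rank (requires ``contig_lengths``); in bin
    mode, the number of bins per taxon. Unclassified totals are included so
    per-rank totals conserve the input sum. Returns the per-rank tallies
    and writes them as a TSV (rank, taxon, value).
    """
    if mode not in ("contig", "bin"):
        raise ValueError("mode must be 'contig' or 'bin'")
    if mode == "contig" and contig_lengths is None:
        raise ValueError("contig mode requires contig lengths")

    with open(named_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            rank_cols = {r: header.index(r) for r in OFFICIAL_RANKS}
        except ValueError as exc:
            raise ValueError(
                f"{named_path}: not an official-rank named file"
            ) from exc
        seen: set[str] = set()
        tallies: dict[str, dict[str, float]] = {r: {} for r in OFFICIAL_RANKS}
        for raw in fh:
            fields = raw.rstrip("\n").split("\t")
            query_id = fields[0]
            if query_id in seen:  # extra lineages of one query count once
                continue
            seen.add(query_id)
            if mode == "contig":
                if query_id not in contig_lengths:
                    raise KeyError(
                        f"contig {query_id!r} absent from the FASTA lengths"
                    )
                weight: float = contig_lengths[query_id]
            else:
                weight = 1
            for rank in OFFICIAL_RANKS:
                taxon = fields[rank_cols[rank]]
                key = taxon if taxon != NOT_CLASSIFIED else NOT_CLASSIFIED
                tallies[rank][key] = tallies[rank].get(key, 0) + weight

    with open(out_path, "w") as out:
        out.write("# rank\ttaxon\t" +
                  ("total_length" if mode == "contig" else "n_bins") + "\n")
        for rank in OFFICIAL_RANKS:
            for taxon in sorted(tallies[rank]):
                value = tallies[rank][taxon]
                out.write(f"{rank}\t{taxon}\t{value:g}\n")
    return tallies
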