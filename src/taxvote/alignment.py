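"""Protein-alignment input: outfmt-6 tables, ORF identifiers, bin membership.

Hits come from a protein aligner run of predicted ORFs against a reference
database, supplied as 12-column BLAST/DIAMOND tabular output. ORF ids follow
the Prodigal convention of appending ``_<n>`` to the contig id.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: outfmt-6 default column order
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

_DECORATION_RE = re.compile(r"^[A-Za-z]+\|([^|]+)\|?")


class TabularFormatError(ValueError):
    """Malformed alignment-table line."""


@dataclass(frozen=True)
class AlignmentHit:
    """One protein alignment of an ORF against a database subject."""

    orf_id: str
    subject_accession: str
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.bitscore < 0 or self.evalue < 0:
            raise ValueError("bitscore and evalue must be non-negative")


@dataclass
class OrfHitGroup:
    """All hits of one ORF, sorted by descending bit-score (stable ties)."""

    orf_id: str
    contig_id: str
    hits: list[AlignmentHit] = field(default_factory=list)


@dataclass
class BinDefinition:
    """A MAG/bin: a named, non-empty set of contig ids."""

    bin_id: str
    contig_ids: set[str]


def parse_orf_id(orf_id: str) -> tuple[str, int]:
    """Split a Prodigal-style ORF id into (contig_id, orf_index).

    Splits on the last underscore when the suffix is an integer; otherwise
    the whole id is the contig id, with index 1 and a logged warning.
    """
    if not orf_id:
        raise ValueError("empty ORF id")
    stem, _, suffix = orf_id.rpartition("_")
    if stem and suffix.isdigit():
        return stem, int(suffix)
    logger.warning(
        "ORF id %r has no integer suffix; treating it as its own contig",
        orf_id,
    )
    return orf_id, 1


def strip_subject_decoration(sseqid: str, pattern: re.Pattern | None = None) -> str:
    """Strip database decorations such as ``ref|P1.1|`` → ``P1.1``.

    The pattern is configurable because decoration conventions differ
    between databases; the default handles the leading ``db|ACC|`` style.
    """
    m = (pattern or _DECORATION_RE).match(sseqid)
    return m.group(1) if m else sseqid


def read_tabular(
    path,
    evalue_cutoff: float = 0.001,
    qseqid_col: int = 0,
    sseqid_col: int = 1,
    evalue_col: int = 10,
    bitscore_col: int = 11,
    n_columns: int = 12,
    decoration_pattern: re.Pattern | None = None,
    tolerant: bool = False,
) -> Iterator[AlignmentHit]:
    """Stream hits from a BLAST/DIAMOND tabular (outfmt 6) file.

    Hits with e-value above ``evalue_cutoff`` are filtered out. With
    ``tolerant`` malformed lines are skipped with a warning instead of
    raising :class:`TabularFormatError`.
    """
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) != n_columns:
                    raise TabularFormatError(
                        f"{path}:{i}: expected {n_columns} columns, "
                        f"got {len(fields)}"
                    )
                try:
                    evalue = float(fields[evalue_col])
                    bitscore = float(fields[bitscore_col])
                except ValueError as exc:
                    raise TabularFormatError(
                        f"{path}:{i}: non-numeric e-value or bit-score"
                    ) from exc
            except TabularFormatError:
                if tolerant:
                    logger.warning("%s:%d: skipping malformed line", path, i)
                    continue
                raise
            if evalue > evalue_cutoff:
                continue
            yield AlignmentHit(
                orf_id=fields[qseqid_col],
                subject_accession=strip_subject_decoration(
                    fields[sseqid_col], decoration_pattern
                ),
                bitscore=bitscore,
                evalue=evalue,
            )


def check_table_depth(r: float, table_depth: float = 50.0) -> bool:
    """Warn when the range parameter exceeds the alignment table's depth.

    Aligners are typically asked to report hits down to some percentage of
    the top bit-score; a supplied table cannot be checked for completeness,
    so if ``r`` exceeds the declared depth the range window may reach past
    the hits actually present. Returns True when the combination is safe.
    """
    if r > table_depth:
        logger.warning(
            "range parameter r=%g exceeds the declared alignment table "
            "depth of %g%%; hits in the window may be missing from the "
            "table", r, table_depth,
        )
        return False
    return True


def group_hits(hits: Iterable[AlignmentHit]) -> dict[str, list[OrfHitGroup]]:
    """Group hits per ORF and attach ORF groups to their contigs.

    Within a group hits are sorted by descending bit-score with stable ties
    (input order preserved). When one ORF aligns to the same subject more
    than once (multiple HSPs), only the highest-scoring line is kept so a
    subject cannot vote twice. Input order does not matter: shuffled input
    yields identical grouping.
    """
    # best HSP per (orf, subject), remembering first-seen order for ties
    best: dict[tuple[str, str], tuple[AlignmentHit, int]] = {}
    orf_order: dict[str, int] = {}
    for i, hit in enumerate(hits):
        orf_order.setdefault(hit.orf_id, len(orf_order))
        key = (hit.orf_id, hit.subject_accession)
        prev = best.get(key)
        if prev is None or hit.bitscore > prev[0].bitscore:
            best[key] = (hit, prev[1] if prev else i)

    per_orf: dict[str, list[tuple[AlignmentHit, int]]] = {}
    for (orf_id, _), (hit, order) in best.items():
        per_orf.setdefault(orf_id, []).append((hit, order))

    out: dict[str, list[OrfHitGroup]] = {}
    for orf_id in sorted(per_orf, key=lambda o: orf_order[o]):
        entries = per_orf[orf_id]
        entries.sort(key=lambda e: (-e[0].bitscore, e[1]))
        contig_id, _ = parse_orf_id(orf_id)
        out.setdefault(contig_id, []).append(
            OrfHitGroup(orf_id=orf_id, contig_id=contig_id,
                        hits=[e[0] for e in entries])
        )
    for groups in out.values():
        groups.sort(key=lambda g: parse_orf_id(g.orf_id)[1])
    return out


class BinMembershipError(ValueError):
    """A contig assigned to more than one bin."""


def load_bins(path_or_dir) -> list[BinDefinition]:
    """Load bin definitions from a directory of FASTA files or a TSV.

    A directory yields one bin per FASTA file (``.fa``/``.fna``/``.fasta``),
    named after the file stem, with contig ids taken from the headers. A
    file is read as a 2-column TSV ``contig_id<TAB>bin_id``. A contig in
    more than one bin raises :class:`BinMembershipError`.
    """
    membership: dict[str, str] = {}
    order: list[str] = []
    if os.path.isdir(path_or_dir):
        for fname in sorted(os.listdir(path_or_dir)):
            stem, ext = os.path.splitext(fname)
            if ext.lower() not in {".fa", ".fna", ".fasta"}:
                continue
            order.append(stem)
            for record in SeqIO.parse(os.path.join(path_or_dir, fname), "fasta"):
                _assign(membership, record.id, stem)
    else:
        with open(path_or_dir, encoding="utf-8") as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                contig_id, bin_id = line.split("\t")[:2]
                if bin_id not in order:
                    order.append(bin_id)
                _assign(membership, contig_id, bin_id)
    bins: dict[str, set[str]] = {b: set() for b in order}
    for contig_id, bin_id in membership.items():
        bins[bin_id].add(contig_id)
    out = [BinDefinition(bin_id=b, contig_ids=c) for b, c in bins.items() if c]
    if len(out) != len(order):
        empty = [b for b in order if not bins[b]]
        logger.warning("empty bin(s) skipped: %s", ", ".join(empty))
    return out


def _assign(membership: dict[str, str], contig_id: str, bin_id: str) -> None:
    prev = membership.get(contig_id)
    if prev is not None and prev != bin_id:
        raise BinMembershipError(
            f"contig {contig_id!r} is in both bin {prev!r} and {bin_id!r}"
        )
    membership[contig_id] = bin_id


def read_protein_ids(protein_fasta) -> dict[str, list[str]]:
    """Read predicted-protein ids (token before first whitespace) per contig.

    Used to count ORFs that have no alignment hits at all, so they can be
    reported with a reason instead of silently vanishing.
    """
    out: dict[str, list[str]] = {}
    for record in SeqIO.parse(protein_fasta, "fasta"):
        contig_id, _ = parse_orf_id(record.id)
        out.setdefault(contig_id, []).append(record.id)
    return out
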