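"""NCBI-style taxonomy: taxdump loading, lineages, LCA, protein→taxon maps.

The taxonomy tree is the coordinate system for all classification. It is
loaded from the standard taxdump dialect (``nodes.dmp``/``names.dmp``,
optionally ``merged.dmp``/``delnodes.dmp``; fields separated by ``\\t|\\t``,
lines terminated by ``\\t|``). Merged taxids are redirected transitively
before any lookup; deleted taxids resolve to a missing marker rather than
raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: The seven official ranks, shallowest first.
OFFICIAL_RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


class TaxdumpError(ValueError):
    """Malformed or structurally invalid taxdump input."""


@dataclass
class TaxonomyTree:
    """Rooted, rank-labelled taxonomy tree.

    Attributes
    ----------
    parent_of : dict
        taxid → parent taxid; the root is its own parent.
    rank_of : dict
        taxid → rank string, verbatim from ``nodes.dmp`` ("no rank" included).
    name_of : dict
        taxid → scientific name; may be partial. Unnamed nodes render as
        ``taxid:<n>``.
    merged : dict
        old taxid → new taxid redirects.
    deleted : set
        taxids known to have been removed from the taxonomy.
    root_id : int
        taxid of the root node.
    """

    parent_of: dict[int, int]
    rank_of: dict[int, str]
    name_of: dict[int, str] = field(default_factory=dict)
    merged: dict[int, int] = field(default_factory=dict)
    deleted: set[int] = field(default_factory=set)
    root_id: int = 1

    def __post_init__(self) -> None:
        self._lineage_cache: dict[int, tuple[int, ...]] = {}
        self.validate()

    # -- structure ----------------------------------------------------------

    def validate(self) -> None:
        """Check rootedness, absence of cycles and orphan parents."""
        if self.parent_of.get(self.root_id) != self.root_id:
            raise TaxdumpError(
                f"root taxid {self.root_id} is not its own parent"
            )
        orphans = sorted(
            {p for p in self.parent_of.values() if p not in self.parent_of}
        )
        if orphans:
            raise TaxdumpError(
                "parent taxids absent from the node table: "
                + ", ".join(map(str, orphans))
            )
        overlap = self.merged.keys() & self.parent_of.keys()
        if overlap:
            raise TaxdumpError(
                "merged taxids also present as nodes: "
                + ", ".join(map(str, sorted(overlap)))
            )
        # cycle detection: walk every node to root with a visited set
        ok: set[int] = {self.root_id}
        for start in self.parent_of:
            path = []
            t = start
            while t not in ok:
                path.append(t)
                t = self.parent_of[t]
                if t in path:
                    raise TaxdumpError(f"cycle in parent chain at taxid {t}")
            ok.update(path)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.parent_of

    def name(self, taxid: int) -> str:
        return self.name_of.get(taxid, f"taxid:{taxid}")

    def resolve(self, taxid: int) -> int | None:
        """Resolve a taxid, following merged redirects transitively.

        Returns ``None`` for deleted or unknown taxids; missing is a value
        here, not an error.
        """
        seen: set[int] = set()
        while taxid not in self.parent_of:
            if taxid in self.deleted or taxid in seen:
                return None
            seen.add(taxid)
            if taxid in self.merged:
                taxid = self.merged[taxid]
            else:
                return None
        return taxid

    def lineage(self, taxid: int) -> tuple[int, ...]:
        """Root-to-taxon path, both endpoints inclusive."""
        resolved = self.resolve(taxid)
        if resolved is None:
            raise KeyError(f"taxid {taxid} does not resolve in the taxonomy")
        cached = self._lineage_cache.get(resolved)
        if cached is not None:
            return cached
        rev = []
        t = resolved
        while t != self.root_id:
            rev.append(t)
            t = self.parent_of[t]
        rev.append(self.root_id)
        lin = tuple(reversed(rev))
        self._lineage_cache[resolved] = lin
        return lin

    def lca(self, taxids: Iterable[int]) -> int:
        """Last common ancestor: the deepest node shared by all lineages."""
        taxids = set(taxids)
        if not taxids:
            raise ValueError("lca of an empty taxid set is undefined")
        it = iter(taxids)
        common = self.lineage(next(it))
        for t in it:
            other = set(self.lineage(t))
            # lineages share a root prefix; keep the common prefix
            keep = 0
            for node in common:
                if node not in other:
                    break
                keep += 1
            common = common[:keep]
        return common[-1]

    def is_ancestor(self, ancestor: int, taxid: int) -> bool:
        """True if ``ancestor`` lies on ``taxid``'s lineage (inclusive)."""
        return ancestor in self.lineage(taxid)

    def official_rank_projection(self, taxid: int) -> dict[str, int]:
        """Map each official rank present in the lineage to its node.

        A "no rank" strain below species projects to the same map as its
        species parent; ranks absent from the lineage are absent from the
        map.
        """
        out: dict[str, int] = {}
        for node in self.lineage(taxid):
            rank = self.rank_of.get(node)
            if rank in _OFFICIAL_SET:
                out[rank] = node
        return out

    def deepest_official(self, taxid: int) -> tuple[str, int] | None:
        """Deepest official (rank, node) on the lineage, or None."""
        best = None
        for node in self.lineage(taxid):
            rank = self.rank_of.get(node)
            if rank in _OFFICIAL_SET:
                best = (rank, node)
        return best


_OFFICIAL_SET = frozenset(OFFICIAL_RANKS)


# -- taxdump parsing --------------------------------------------------------


def _iter_dmp(path) -> Iterable[tuple[int, list[str]]]:
    """Yield (line number, fields) from a taxdump-dialect file."""
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if not line.endswith("\t|"):
                raise TaxdumpError(
                    f"{path}:{i}: line does not end with the "
                    "taxdump terminator '\\t|'"
                )
            yield i, line[: -len("\t|")].split("\t|\t")


def load_taxdump(
    nodes_path,
    names_path=None,
    merged_path=None,
    delnodes_path=None,
) -> TaxonomyTree:
    """Load a taxonomy from taxdump files.

    ``names_path`` is filtered to the "scientific name" class; when the file
    has fewer than four columns every line is taken as a name. Raises
    :class:`TaxdumpError` on malformed lines (with line number), orphan
    parents or cycles.
    """
    parent_of: dict[int, int] = {}
    rank_of: dict[int, str] = {}
    root_id = None
    for i, fields in _iter_dmp(nodes_path):
        if len(fields) < 3:
            raise TaxdumpError(
                f"{nodes_path}:{i}: expected at least 3 fields, "
                f"got {len(fields)}"
            )
        try:
            taxid, parent = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise TaxdumpError(f"{nodes_path}:{i}: non-integer taxid") from exc
        parent_of[taxid] = parent
        rank_of[taxid] = fields[2]
        if taxid == parent:
            root_id = taxid
    if root_id is None:
        raise TaxdumpError(f"{nodes_path}: no root node (taxid == parent)")

    name_of: dict[int, str] = {}
    if names_path is not None:
        for i, fields in _iter_dmp(names_path):
            if len(fields) < 2:
                raise TaxdumpError(
                    f"{names_path}:{i}: expected at least 2 fields"
                )
            if len(fields) >= 4 and fields[3] != "scientific name":
                continue
            try:
                name_of[int(fields[0])] = fields[1]
            except ValueError as exc:
                raise TaxdumpError(
                    f"{names_path}:{i}: non-integer taxid"
                ) from exc

    merged: dict[int, int] = {}
    if merged_path is not None:
        for i, fields in _iter_dmp(merged_path):
            if len(fields) < 2:
                raise TaxdumpError(
                    f"{merged_path}:{i}: expected 2 fields"
                )
            merged[int(fields[0])] = int(fields[1])

    deleted: set[int] = set()
    if delnodes_path is not None:
        for i, fields in _iter_dmp(delnodes_path):
            deleted.add(int(fields[0]))

    return TaxonomyTree(
        parent_of=parent_of,
        rank_of=rank_of,
        name_of=name_of,
        merged=merged,
        deleted=deleted,
        root_id=root_id,
    )


def write_taxdump(tree: TaxonomyTree, directory) -> None:
    """Serialize a tree to ``nodes.dmp``/``names.dmp`` (+merged/delnodes)."""
    import os

    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "nodes.dmp"), "w") as fh:
        for taxid in sorted(tree.parent_of):
            fh.write(
                f"{taxid}\t|\t{tree.parent_of[taxid]}\t|\t"
                f"{tree.rank_of[taxid]}\t|\n"
            )
    with open(os.path.join(directory, "names.dmp"), "w") as fh:
        for taxid in sorted(tree.name_of):
            fh.write(
                f"{taxid}\t|\t{tree.name_of[taxid]}\t|\t\t|\t"
                "scientific name\t|\n"
            )
    if tree.merged:
        with open(os.path.join(directory, "merged.dmp"), "w") as fh:
            for old in sorted(tree.merged):
                fh.write(f"{old}\t|\t{tree.merged[old]}\t|\n")
    if tree.deleted:
        with open(os.path.join(directory, "delnodes.dmp"), "w") as fh:
            for taxid in sorted(tree.deleted):
                fh.write(f"{taxid}\t|\n")


# -- protein accession → taxid mapping --------------------------------------


@dataclass
class ProteinTaxonMap:
    """Protein accession → taxid lookup.

    Keys are stored with and without version suffix; the versioned form is
    preferred on lookup.
    """

    taxid_of: dict[str, int]

    def __post_init__(self) -> None:
        self._bare: dict[str, int] = {}
        for acc, taxid in self.taxid_of.items():
            if "." in acc:
                self._bare.setdefault(acc.rsplit(".", 1)[0], taxid)

    def get(self, accession: str) -> int | None:
        hit = self.taxid_of.get(accession)
        if hit is not None:
            return hit
        if "." in accession:
            hit = self.taxid_of.get(accession.rsplit(".", 1)[0])
            if hit is not None:
                return hit
        return self._bare.get(accession)

    def __len__(self) -> int:
        return len(self.taxid_of)


def build_protein_map(
    accession2taxid_path,
    tree: TaxonomyTree,
    lca_correct: bool = True,
    accession_column: str | None = None,
    taxid_column: str | None = None,
) -> ProteinTaxonMap:
    """Build a corrected accession→taxid map from a prot.accession2taxid file.

    Accepts the 4-column NCBI layout (``accession``, ``accession.version``,
    ``taxid``, ``gi``) and a minimal 2-column (accession, taxid) layout, both
    tab-delimited with a header. An accession occurring on multiple lines
    with different taxids maps to the LCA of all of them when ``lca_correct``
    is on; with it off, the first occurrence wins. Lines whose taxid does not
    resolve are dropped with a logged warning count.
    """
    with open(accession2taxid_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c: i for i, c in enumerate(header)}
        if accession_column is None:
            accession_column = (
                "accession.version" if "accession.version" in cols
                else "accession"
            )
        if taxid_column is None:
            taxid_column = "taxid"
        if accession_column not in cols or taxid_column not in cols:
            raise ValueError(
                f"{accession2taxid_path}: required columns "
                f"{accession_column!r}/{taxid_column!r} not in header "
                f"{header}"
            )
        acc_i, tax_i = cols[accession_column], cols[taxid_column]
        taxids_seen: dict[str, set[int]] = {}
        first: dict[str, int] = {}
        dropped = 0
        for raw in fh:
            fields = raw.rstrip("\n").split("\t")
            if len(fields) <= max(acc_i, tax_i):
                continue
            acc = fields[acc_i]
            taxid = tree.resolve(int(fields[tax_i]))
            if taxid is None:
                dropped += 1
                continue
            taxids_seen.setdefault(acc, set()).add(taxid)
            first.setdefault(acc, taxid)
    if dropped:
        logger.warning(
            "%d line(s) in %s dropped: taxid does not resolve",
            dropped, accession2taxid_path,
        )
    taxid_of: dict[str, int] = {}
    for acc, taxids in taxids_seen.items():
        if lca_correct and len(taxids) > 1:
            taxid_of[acc] = tree.lca(taxids)
        else:
            taxid_of[acc] = first[acc]
    return ProteinTaxonMap(taxid_of=taxid_of)


def write_accession2taxid(mapping: Mapping[str, int], path) -> None:
    """Write a 4-column NCBI-layout prot.accession2taxid file."""
    with open(path, "w") as fh:
        fh.write("accession\taccession.version\ttaxid\tgi\n")
        for acc in sorted(mapping):
            bare = acc.rsplit(".", 1)[0] if "." in acc else acc
            fh.write(f"{bare}\t{acc}\t{mapping[acc]}\t0\n")
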