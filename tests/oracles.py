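"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library's vote/assign code path: support is
computed by direct summation over every taxonomy node, and qualifying
terminals by explicit descendant checks.
"""

from __future__ import annotations


def brute_support(orfs, tree):
    """Per-node support by direct summation over all taxonomy nodes."""
    support = {}
    for node in tree.parent_of:
        s = sum(
            o.registered_bitscore
            for o in orfs
            if o.classified and node in tree.lineage(o.lca_taxid)
        )
        if s > 0:
            support[node] = s
    return support


def brute_assign_terminals(orfs, f, tree, rel_eps=1e-9):
    """Deepest qualifying nodes under the mbs threshold, brute force."""
    support = brute_support(orfs, tree)
    b_sum = sum(o.registered_bitscore for o in orfs if o.classified)
    if b_sum <= 0:
        return set(), support, 0.0
    mbs = f * b_sum
    qualifying = {t for t, s in support.items() if s >= mbs * (1 - rel_eps)}
    terminals = {
        t for t in qualifying
        if not any(u != t and t in tree.lineage(u) for u in qualifying)
    }
    return terminals, support, b_sum


def random_orf_classifications(tree, rng, n_orfs):
    """Random classified ORFs over arbitrary taxonomy nodes."""
    from taxvote.classify import OrfClassification

    nodes = sorted(tree.parent_of)
    out = []
    for i in range(n_orfs):
        taxid = int(nodes[int(rng.integers(0, len(nodes)))])
        score = float(rng.uniform(30, 500))
        out.append(OrfClassification(
            orf_id=f"q_{i + 1}", contig_id="q", lca_taxid=taxid,
            registered_bitscore=score, n_hits_in_range=1,
        ))
    return out
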