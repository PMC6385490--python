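"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration and literal
expansion — and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import itertools

IUPAC_NT_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_expand_match(pattern: str, sequence: str) -> list[int]:
    """Expand the degenerate pattern into all literal strings and search each."""
    literals = ["".join(p) for p in
                itertools.product(*(IUPAC_NT_SETS[c] for c in pattern.upper()))]
    seq = sequence.upper()
    hits = set()
    for lit in literals:
        start = 0
        while True:
            i = seq.find(lit, start)
            if i < 0:
                break
            hits.add(i)
            start = i + 1
    return sorted(hits)


def enumerate_splice_chains(cds: str, region: str, min_intron: int = 40,
                            ) -> list[list[tuple[int, int]]]:
    """All chains of exact CDS segments whose gaps are GT..AG introns of
    length ≥ min_intron.  Exponential; for small inputs only."""
    n, m = len(cds), len(region)
    chains: list[list[tuple[int, int]]] = []

    def rec(ci: int, g: int, exons: list[tuple[int, int]]) -> None:
        # current exon starts at cds index ci, genomic position g
        for L in range(1, n - ci + 1):
            if region[g:g + L] != cds[ci:ci + L]:
                # an exact exon must match base by base; once a mismatch
                # appears no longer exon starting here can match
                break
            if ci + L == n:
                chains.append(exons + [(g, g + L)])
                continue
            d = g + L  # donor position
            if region[d:d + 2] != "GT":
                continue
            for e in range(d + min_intron, m + 1):
                if region[e - 2:e] == "AG" and e < m:
                    rec(ci + L, e, exons + [(g, g + L)])

    for g0 in range(m):
        if region[g0] == cds[0]:
            rec(0, g0, [])
    return chains


def min_intron_chains(cds: str, region: str, min_intron: int = 40):
    chains = enumerate_splice_chains(cds, region, min_intron)
    if not chains:
        return None, []
    k = min(len(c) - 1 for c in chains)
    return k, [c for c in chains if len(c) - 1 == k]


# --------------------------------------------------------------------------
# exhaustive parsimony oracles

def exhaustive_min_loss(tree, tip_counts: dict[str, int], ancestral: int) -> int:
    """Minimum total loss magnitude over all monotone internal labelings."""
    internals = [n for n in tree.postorder() if not n.is_leaf and n is not tree.root]
    best = [None]

    def total(assign: dict) -> int:
        t = 0

        def value(node):
            if node.is_leaf:
                return tip_counts.get(node.label)
            if node is tree.root:
                return ancestral
            return assign[node.branch_id]

        def rec(node, parent_val):
            nonlocal t
            v = value(node)
            if v is None:
                v = parent_val
            if v > parent_val:
                return None
            t += parent_val - v
            for c in node.children:
                if rec(c, v) is None:
                    return None
            return t

        t = 0
        for c in tree.root.children:
            if rec(c, ancestral) is None:
                return -1
        return t

    for combo in itertools.product(range(ancestral + 1), repeat=len(internals)):
        assign = {n.branch_id: v for n, v in zip(internals, combo)}
        t = total(assign)
        if t >= 0 and (best[0] is None or t < best[0]):
            best[0] = t
    return best[0]


def random_small_tree(rng, n_leaves: int):
    """Random rooted binary tree as a Newick string over labels a, b, c…"""
    labels = [chr(ord("a") + i) for i in range(n_leaves)]
    nodes = list(labels)
    while len(nodes) > 1:
        i = int(rng.integers(0, len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(0, len(nodes)))
        b = nodes.pop(j)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"
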