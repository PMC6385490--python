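"""Flanking-gene contexts, syntenic slots and the presence/vestige matrix.

A focal locus is characterized by the ordered symbols of its annotated
neighbor genes.  Loci from different species are assigned to the same
*syntenic slot* when they share enough anchors in a consistent relative
order; the species × slot matrix of occupant states {full, vestige, absent}
is the substrate for event inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_io import AnnotatedGenome, GeneRecord, RetrotraceError
from .genemodel import GeneModel, VestigeState

SENTINEL = "<end>"  # chromosome end; never counts as an anchor


@dataclass
class SyntenyContext:
    """Ordered flanking-gene signature of one focal locus."""

    species_id: str
    chromosome: str
    interval: tuple[int, int]
    strand: str
    occupant: GeneModel | VestigeState
    upstream: list[tuple[str, str]]    # (symbol, strand), nearest first, gene sense
    downstream: list[tuple[str, str]]
    host_insertion: tuple[str, int, str] | None = None

    def anchors_genomic_order(self) -> list[str]:
        """Anchor symbols left→right on the chromosome (sentinels dropped)."""
        if self.strand == "+":
            left = [s for s, _ in reversed(self.upstream)]
            right = [s for s, _ in self.downstream]
        else:
            left = [s for s, _ in reversed(self.downstream)]
            right = [s for s, _ in self.upstream]
        return [s for s in left + right if s != SENTINEL]


@dataclass
class PresenceMatrix:
    """Species × slot table of occupant states."""

    table: pd.DataFrame                    # cells in {"full", "vestige", "absent"}
    slot_anchors: dict[str, list[str]] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.table.index)

    @property
    def slots(self) -> list[str]:
        return list(self.table.columns)


def _host_intron_ordinal(host: GeneRecord, pos: int) -> int | None:
    """1-based ordinal, in the host's transcription direction, of the intron
    containing genomic position ``pos``."""
    n = len(host.exons)
    for gi in range(n - 1):
        if host.exons[gi][1] <= pos < host.exons[gi + 1][0]:
            return gi + 1 if host.strand == "+" else (n - 1) - gi
    return None


def extract_context(genome: AnnotatedGenome, chromosome: str,
                    interval: tuple[int, int], strand: str,
                    occupant: GeneModel | VestigeState, k: int = 3,
                    exclude_symbols: set[str] | None = None) -> SyntenyContext:
    """Up to ``k`` flanking gene symbols per side of a focal locus.

    Genes overlapping the locus are not neighbors; a gene whose intron
    contains the locus is reported as ``host_insertion`` with its 1-based
    intron ordinal and the locus orientation relative to the host.  Short
    neighbor lists at chromosome ends are padded with a sentinel.
    """
    lo, hi = interval
    host_insertion = None
    left: list[tuple[str, str]] = []
    right: list[tuple[str, str]] = []
    for g in genome.genes_on(chromosome):
        if exclude_symbols and g.symbol in exclude_symbols:
            continue
        if g.end <= lo:
            left.append((g.symbol, g.strand))
        elif g.start >= hi:
            right.append((g.symbol, g.strand))
        else:
            ordinal = _host_intron_ordinal(g, lo)
            if ordinal is not None and hi <= g.end:
                rel = "same" if g.strand == strand else "opposite"
                host_insertion = (g.symbol, ordinal, rel)
    left = left[::-1]  # nearest first

    def pad(lst):
        return (lst + [(SENTINEL, ".")] * k)[:k]

    if strand == "+":
        upstream, downstream = pad(left), pad(right)
    else:
        upstream, downstream = pad(right), pad(left)
    return SyntenyContext(genome.species_id, chromosome, interval, strand,
                          occupant, upstream, downstream, host_insertion)


def _order_consistent(a: list[str], b: list[str]) -> int:
    """Number of shared anchors if their relative order agrees, else 0."""
    common = [s for s in a if s in b]
    if len(common) < 1:
        return 0
    order_b = [s for s in b if s in common]
    return len(common) if common == order_b else 0


def match_slots(contexts: list[SyntenyContext], min_anchors: int = 2,
                ) -> dict[int, str]:
    """Assign each context to a slot id (union-find over anchor sharing).

    Two contexts land in the same slot iff they share at least
    ``min_anchors`` anchors whose relative genomic order is consistent;
    orientation differences are tolerated, order reversals are not.  The slot
    id is the lexicographically smallest anchor symbol in the slot.
    """
    if not contexts:
        return {}
    n = len(contexts)
    anchors = [c.anchors_genomic_order() for c in contexts]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            shared = _order_consistent(anchors[i], anchors[j])
            if shared >= min_anchors:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    assignment: dict[int, str] = {}
    taken: dict[str, int] = {}
    ordered = sorted(groups.values(),
                     key=lambda ms: sorted((contexts[m].species_id,
                                            contexts[m].chromosome,
                                            contexts[m].interval) for m in ms))
    for members in ordered:
        pool = sorted({s for m in members for s in anchors[m]})
        slot_id = pool[0] if pool else f"unanchored:{contexts[members[0]].chromosome}"
        # distinct groups may share a smallest anchor (e.g. an order-reversed
        # context); suffix deterministically to keep slot ids unique
        taken[slot_id] = taken.get(slot_id, 0) + 1
        if taken[slot_id] > 1:
            slot_id = f"{slot_id}~{taken[slot_id]}"
        for m in members:
            assignment[m] = slot_id
    return assignment


def build_presence_matrix(contexts: list[SyntenyContext],
                          assignment: dict[int, str],
                          species: list[str] | None = None) -> PresenceMatrix:
    """Species × slot matrix: full / vestige / absent.

    A cell is ``full`` when the occupant is a mapped gene model, ``vestige``
    for fragment or short_fragment states, ``absent`` otherwise (including
    species with no context at the slot).  Conflicting duplicate cells raise.
    """
    all_species = sorted(species or {c.species_id for c in contexts})
    slots = sorted(set(assignment.values()))
    cells: dict[tuple[str, str], str] = {}
    slot_anchors: dict[str, set[str]] = {s: set() for s in slots}
    for i, ctx in enumerate(contexts):
        slot = assignment[i]
        slot_anchors[slot].update(ctx.anchors_genomic_order())
        occ = ctx.occupant
        if isinstance(occ, GeneModel):
            state = "full"
        elif isinstance(occ, VestigeState) and occ.state in ("full",):
            state = "full"
        elif isinstance(occ, VestigeState) and occ.state in ("fragment", "short_fragment"):
            state = "vestige"
        else:
            state = "absent"
        key = (ctx.species_id, slot)
        if key in cells and cells[key] != state:
            # a full-length copy outranks a co-sited remnant (tandem copies)
            if "full" in (cells[key], state):
                cells[key] = "full"
            else:
                raise RetrotraceError(f"conflicting duplicate cell {key}: "
                                      f"{cells[key]} vs {state}")
        else:
            cells[key] = state
    table = pd.DataFrame("absent", index=all_species, columns=slots)
    for (sp, slot), state in cells.items():
        if sp in table.index:
            table.loc[sp, slot] = state
    return PresenceMatrix(table, {s: sorted(a) for s, a in slot_anchors.items()})


def count_daughter_slots(matrix: PresenceMatrix, parent_slot: str) -> int:
    """Distinct non-parent slots with at least one full occupant."""
    if parent_slot not in matrix.table.columns:
        raise RetrotraceError(f"unknown parent slot {parent_slot!r}")
    n = 0
    for slot in matrix.table.columns:
        if slot == parent_slot:
            continue
        if (matrix.table[slot] == "full").any():
            n += 1
    return n
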