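"""Forward simulator of a small clade carrying a focal multi-exon gene.

The simulator evolves miniature genomes down a species tree.  Each genome is
a set of short chromosomes, one per *synteny slot*: an ordered run of
single-exon neighbor (anchor) genes with an insertion point between two of
them, or a multi-exon host gene for intragenic insertions.  The ancestral
focal gene has nine exons and eight GT-AG introns, a ~200 bp promoter block
(TATA box plus klf3/17 and foxa3 binding motifs), and a protein with the two
astacin active-site consensus motifs and six cysteines.

Planted events edit the genome on specific branches:

``translocation_gain``
    retrocopy of a source copy with the 3'-most *n* introns precisely
    excised, inserted at a destination slot, with or without its promoter;
``intron_loss``
    in-place precise excision of the 3'-most *n* introns of a copy;
``pseudogenization``
    graded decay of a copy (fragment / short fragment / erased);
``copy_loss``
    complete erasure of a copy.

Neutral point substitution acts everywhere else, with purifying selection on
functional copies: splice dinucleotides, promoter motifs, start/stop codons
are held fixed and nonsense substitutions are rejected — decayed vestiges
drift freely.  Every run is a pure function of the seed.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import (AnnotatedGenome, GeneRecord, RetrotraceError,
                      SpeciesTree, match_iupac, read_newick, revcomp, translate)

PROMOTER_LEN = 200
TATA = "TATAAAT"          # matches the TATAWAW consensus
KLF_SITE = "CACCC"
FOXA3_SITE = "TGTTTACTTA"
INDISPENSABLE = (-192, -91)  # offsets of the promoter subregion required for expression

_CODONS = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_FILLER_AA = "ADEFGIKLNPQRTVWY"  # no C (cysteine budget), no H/S/M (motif anchors)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


# --------------------------------------------------------------------------
# ancestral focal gene

@dataclass
class AncestralGene:
    """Designed ancestral focal gene: sequences and coordinates of features."""

    exons: list[str]            # spliced order
    introns: list[str]
    promoter: str               # PROMOTER_LEN bases, 5'→3', ends at the TSS
    tata_offset: int            # offsets relative to the TSS (negative)
    klf_offset: int
    foxa3_offset: int

    @property
    def cds(self) -> str:
        return "".join(self.exons)

    @property
    def protein(self) -> str:
        return translate(self.cds)

    def genomic(self) -> str:
        """Exon/intron interleave (no promoter)."""
        parts = [self.exons[0]]
        for intr, ex in zip(self.introns, self.exons[1:]):
            parts.append(intr)
            parts.append(ex)
        return "".join(parts)


def _design_protein(rng: np.random.Generator, length: int = 270) -> str:
    site1 = "HE??H??GF?HE??R?DR"
    site2 = "S?MHY"
    while True:
        aa = ["M"] + [_FILLER_AA[i] for i in rng.integers(0, len(_FILLER_AA), size=length - 1)]
        p1, p2 = 110, 200
        for pos, pat in ((p1, site1), (p2, site2)):
            for k, sym in enumerate(pat):
                aa[pos + k] = _FILLER_AA[rng.integers(0, len(_FILLER_AA))] if sym == "?" else sym
        # exactly six cysteines, clear of the active sites
        cys_pool = [i for i in range(10, length - 5)
                    if not (p1 - 1 <= i < p1 + len(site1) + 1 or p2 - 1 <= i < p2 + len(site2) + 1)]
        for i in rng.choice(cys_pool, size=6, replace=False):
            aa[i] = "C"
        prot = "".join(aa)
        hits1 = match_iupac("HEXXHXXGFXHEXXRXDR", prot, "aa")
        hits2 = match_iupac("SXMHY", prot, "aa")
        if len(hits1) == 1 and len(hits2) == 1 and prot.count("C") == 6:
            return prot


def _design_promoter(rng: np.random.Generator) -> tuple[str, int, int, int]:
    """A PROMOTER_LEN block with a TATA box and klf/foxa3 sites planted in the
    indispensable subregion; the TATA is the 3'-most match in the search
    window so it is recovered unambiguously."""
    tata_off = -31
    while True:
        block = list(_rand_seq(rng, PROMOTER_LEN))
        klf_off = int(rng.integers(-190, -160))
        foxa_off = int(rng.integers(-150, -106))
        for off, site in ((tata_off, TATA), (klf_off, KLF_SITE), (foxa_off, FOXA3_SITE)):
            i = PROMOTER_LEN + off
            block[i:i + len(site)] = site
        seq = "".join(block)
        win = seq[PROMOTER_LEN - 50:PROMOTER_LEN - 20 + len(TATA)]
        tata_hits = match_iupac("TATAWAW", win)
        if [h for h in tata_hits if h != (50 - 31)]:
            continue  # a chance TATA inside the search window: redraw
        lo, hi = INDISPENSABLE
        sub = seq[PROMOTER_LEN + lo:PROMOTER_LEN + hi + 1]
        if match_iupac("CWCCC", sub) and match_iupac("TGTTTRCWYW", sub):
            return seq, tata_off, klf_off, foxa_off


def _can_slide(exon_left: str, intron: str, exon_right: str, kmax: int = 12) -> bool:
    """True when the intron window could shift without changing the spliced
    product — an ambiguity the generator refuses to plant."""
    for k in range(2, kmax + 1):
        # left slide by k: new intron = exon_left[-k:] + intron[:-k]
        if len(exon_left) >= k + 1 and exon_left[-k:] == intron[-k:] \
                and exon_left[-k:][:2] == "GT" and intron[-k - 2:-k] == "AG":
            return True
        # right slide by k: new intron = intron[k:] + exon_right[:k]
        if len(exon_right) >= k + 1 and exon_right[:k] == intron[:k] \
                and intron[k:k + 2] == "GT" and exon_right[:k][-2:] == "AG":
            return True
    return False


def make_ancestral_he_gene(rng: np.random.Generator | int = 0) -> AncestralGene:
    """Design the ancestral focal gene: 9 exons, 8 GT-AG introns, a CDS whose
    protein carries both active-site consensus motifs and six cysteines, and
    a 200 bp promoter block with TATA, klf and foxa3 sites."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    protein = _design_protein(rng)
    cds = "".join(_CODONS[a] for a in protein) + "TAA"
    n_ex = 9
    base = 60
    extra = rng.multinomial(len(cds) - base * n_ex, [1 / n_ex] * n_ex)
    sizes = [base + int(x) for x in extra]
    exons, pos = [], 0
    for s in sizes:
        exons.append(cds[pos:pos + s])
        pos += s
    introns = []
    for i in range(n_ex - 1):
        while True:
            L = int(rng.integers(60, 121))
            intron = "GT" + _rand_seq(rng, L - 4) + "AG"
            if not _can_slide(exons[i], intron, exons[i + 1]):
                introns.append(intron)
                break
    promoter, t, k, f = _design_promoter(rng)
    return AncestralGene(exons, introns, promoter, t, k, f)


# --------------------------------------------------------------------------
# slots, events, parameters

@dataclass
class HostSpec:
    symbol: str
    n_exons: int = 16


@dataclass
class SlotSpec:
    """Layout of one synteny-slot chromosome in the ancestral genome."""

    name: str
    chrom: str
    anchors: list[tuple[str, str]]          # (symbol, strand) left → right
    insert_after: int = 0                   # insertion between anchors[i] and [i+1]
    insert_strand: str = "+"                # strand of an inserted focal copy
    host: HostSpec | None = None            # intragenic destination instead
    host_intron_ordinal: int = 14           # 1-based, transcription direction
    host_orientation: str = "opposite"      # copy strand relative to host


@dataclass
class PlannedEvent:
    branch_id: str
    kind: str                    # translocation_gain | intron_loss | pseudogenization | copy_loss
    slot: str                    # destination (gain) or target copy's slot
    source_slot: str = ""
    introns_removed: int = 0
    promoter_carryover: bool = True
    stage: str = "fragment"      # pseudogenization decay stage


@dataclass
class LogEntry:
    branch_id: str
    kind: str
    payload: dict


@dataclass
class SimParams:
    """Study conditions for one simulated clade."""

    seed: int = 0
    subst_rate: float = 0.0      # substitutions per site per branch
    n_neighbor_genes: int = 3    # anchors per flank on generic slots
    slots: list[SlotSpec] = field(default_factory=list)
    parent_slot: str = "parent"
    parent_strand: str = "+"
    events: list[PlannedEvent] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.subst_rate <= 1.0:
            raise RetrotraceError("subst_rate must be a probability")


@dataclass
class FocalCopy:
    """Ground-truth record of one focal-family copy in one genome."""

    slot: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    promoter: tuple[int, int] | None
    carried: bool                # promoter descends from the ancestral block
    functional: bool = True
    stage: str = "none"          # none | fragment | short | erased

    @property
    def span(self) -> tuple[int, int]:
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        if self.promoter:
            lo = min(lo, self.promoter[0])
            hi = max(hi, self.promoter[1])
        return lo, hi


@dataclass
class SimResult:
    tree: SpeciesTree
    genomes: dict[str, AnnotatedGenome]
    event_log: list[LogEntry]
    truth: dict[str, list[FocalCopy]]
    ancestral: AncestralGene
    params: SimParams


def default_slots(n_dest: int = 3, n_neighbors: int = 3) -> list[SlotSpec]:
    """Generic layout: one parent slot plus ``n_dest`` destination slots."""
    slots = [SlotSpec("parent", "chr_parent",
                      [(f"panc{i}", "+" if i % 2 else "-") for i in range(2 * n_neighbors)],
                      insert_after=n_neighbors - 1)]
    for d in range(n_dest):
        slots.append(SlotSpec(f"dest{d}", f"chr_dest{d}",
                              [(f"d{d}anc{i}", "+" if (i + d) % 2 else "-")
                               for i in range(2 * n_neighbors)],
                              insert_after=n_neighbors - 1,
                              insert_strand="+" if d % 2 else "-"))
    return slots


# --------------------------------------------------------------------------
# mutable lineage state

class _Lineage:
    def __init__(self, chroms: dict[str, str], genes: list[GeneRecord],
                 copies: list[FocalCopy],
                 promoter_features: list[tuple[int, int]] | None = None):
        self.chroms = chroms
        self.genes = genes
        self.copies = copies
        # (offset relative to TSS, length) of selectively constrained promoter
        # features; identical for every carried promoter (no indels occur)
        self.promoter_features = promoter_features or []

    def clone(self) -> "_Lineage":
        return _Lineage(dict(self.chroms),
                        _copy.deepcopy(self.genes),
                        _copy.deepcopy(self.copies),
                        list(self.promoter_features))

    # -- coordinate-preserving edits --------------------------------------
    def _shift(self, chrom: str, at: int, delta: int) -> None:
        def mv(iv):
            s, e = iv
            return (s + delta if s >= at else s, e + delta if e > at else e)

        for g in self.genes:
            if g.chromosome == chrom:
                g.exons = [mv(iv) for iv in g.exons]
        for c in self.copies:
            if c.chrom == chrom:
                c.exons = [mv(iv) for iv in c.exons]
                if c.promoter:
                    c.promoter = mv(c.promoter)

    def insert(self, chrom: str, pos: int, seq: str) -> None:
        s = self.chroms[chrom]
        self.chroms[chrom] = s[:pos] + seq + s[pos:]
        self._shift(chrom, pos, len(seq))

    def replace(self, chrom: str, start: int, end: int, seq: str) -> None:
        s = self.chroms[chrom]
        self.chroms[chrom] = s[:start] + seq + s[end:]
        delta = len(seq) - (end - start)
        if delta:
            self._shift(chrom, end, delta)

    def gene_by_symbol(self, symbol: str) -> GeneRecord:
        for g in self.genes:
            if g.symbol == symbol:
                return g
        raise RetrotraceError(f"no gene with symbol {symbol!r}")

    def copy_at(self, slot: str) -> FocalCopy:
        for c in self.copies:
            if c.slot == slot and c.stage != "erased":
                return c
        raise RetrotraceError(f"no focal copy at slot {slot!r}")


# --------------------------------------------------------------------------
# building the ancestor

_FOCAL_SYMBOL = "hce"


def _build_anchor_gene(rng, gid, symbol, chrom, strand, pos, length) -> tuple[GeneRecord, str]:
    seq = _rand_seq(rng, length)
    return GeneRecord(gid, symbol, chrom, strand, [(pos, pos + length)]), seq


def _build_host_gene(rng, gid, symbol, chrom, strand, pos, n_exons) -> tuple[GeneRecord, str]:
    parts, exons, cur = [], [], pos
    for i in range(n_exons):
        ex = _rand_seq(rng, int(rng.integers(90, 140)))
        exons.append((cur, cur + len(ex)))
        parts.append(ex)
        cur += len(ex)
        if i < n_exons - 1:
            intr = "GT" + _rand_seq(rng, int(rng.integers(70, 110)) - 4) + "AG"
            parts.append(intr)
            cur += len(intr)
    return GeneRecord(gid, symbol, chrom, strand, exons), "".join(parts)


def _focal_insert_seq(gene_seq: str, promoter: str | None, strand: str,
                      ) -> tuple[str, int, int | None]:
    """Sequence to splice in, plus offsets (within the insert, plus strand) of
    the gene start and the promoter start."""
    block = (promoter or "") + gene_seq
    if strand == "+":
        prom_off = 0 if promoter else None
        return block, len(promoter or ""), prom_off
    rc = revcomp(block)
    # on '-', the gene occupies the left part of the insert
    gene_off = 0
    prom_off = len(gene_seq) if promoter else None
    return rc, gene_off, prom_off


def _ancestor(rng: np.random.Generator, params: SimParams,
              anc: AncestralGene) -> _Lineage:
    chroms: dict[str, str] = {}
    genes: list[GeneRecord] = []
    copies: list[FocalCopy] = []
    gid = 0
    for slot in params.slots:
        parts: list[str] = []
        cur = 0
        order: list[tuple[str, str, str]] = []  # (kind, symbol, strand)
        for i, (sym, strand) in enumerate(slot.anchors):
            order.append(("anchor", sym, strand))
            if slot.host is None and i == slot.insert_after and slot.name == params.parent_slot:
                order.append(("focal", _FOCAL_SYMBOL, params.parent_strand))
        if slot.host is not None:
            mid = len(order) // 2
            order.insert(mid, ("host", slot.host.symbol, "+"))
        for kind, sym, strand in order:
            spacer = _rand_seq(rng, int(rng.integers(150, 300)))
            parts.append(spacer)
            cur += len(spacer)
            if kind == "anchor":
                g, seq = _build_anchor_gene(rng, f"g{gid}", sym, slot.chrom,
                                            strand, cur, int(rng.integers(300, 500)))
            elif kind == "host":
                g, seq = _build_host_gene(rng, f"g{gid}", sym, slot.chrom,
                                          strand, cur, slot.host.n_exons)
            else:  # focal gene with promoter at the parent slot
                gene_seq = anc.genomic()
                insert, gene_off, prom_off = _focal_insert_seq(gene_seq, anc.promoter, strand)
                exon_ivs = _exon_intervals(anc, cur + gene_off, strand)
                prom_iv = (cur + prom_off, cur + prom_off + PROMOTER_LEN)
                copies.append(FocalCopy(slot.name, slot.chrom, strand,
                                        exon_ivs, prom_iv, carried=True))
                g = GeneRecord(f"g{gid}", _FOCAL_SYMBOL, slot.chrom, strand, list(exon_ivs))
                seq = insert
            gid += 1
            parts.append(seq)
            cur += len(seq)
            genes.append(g)
        tail = _rand_seq(rng, int(rng.integers(150, 300)))
        parts.append(tail)
        chroms[slot.chrom] = "".join(parts)
    return _Lineage(chroms, genes, copies)


def _exon_intervals(anc_like, offset: int, strand: str,
                    exons: list[str] | None = None,
                    introns: list[str] | None = None) -> list[tuple[int, int]]:
    """Genomic exon intervals of an exon/intron interleave placed at offset.
    For '-' the spliced order is right-to-left on the genome."""
    exs = exons if exons is not None else anc_like.exons
    ins = introns if introns is not None else anc_like.introns
    lens = []
    for i, e in enumerate(exs):
        lens.append(("e", len(e)))
        if i < len(ins):
            lens.append(("i", len(ins[i])))
    if strand == "-":
        lens.reverse()
    out, cur = [], offset
    for kind, L in lens:
        if kind == "e":
            out.append((cur, cur + L))
        cur += L
    return out


# --------------------------------------------------------------------------
# event application

def _copy_gene_parts(lin: _Lineage, cp: FocalCopy) -> tuple[list[str], list[str]]:
    """Current exon and intron sequences of a copy, in spliced order."""
    seq = lin.chroms[cp.chrom]
    ivs = sorted(cp.exons)
    exs = [seq[s:e] for s, e in ivs]
    ins = [seq[ivs[i][1]:ivs[i + 1][0]] for i in range(len(ivs) - 1)]
    if cp.strand == "-":
        exs = [revcomp(x) for x in reversed(exs)]
        ins = [revcomp(x) for x in reversed(ins)]
    return exs, ins


def _splice_out_introns(exs: list[str], ins: list[str], n: int) -> tuple[list[str], list[str]]:
    """Precisely excise the 3'-most n introns (merging the flanking exons)."""
    if n > len(ins):
        raise RetrotraceError(f"cannot remove {n} introns from {len(ins)}")
    for _ in range(n):
        ins.pop()
        last = exs.pop()
        exs[-1] = exs[-1] + last
    return exs, ins


def _interleave(exs: list[str], ins: list[str]) -> str:
    parts = [exs[0]]
    for i, x in enumerate(exs[1:]):
        parts.append(ins[i])
        parts.append(x)
    return "".join(parts)


def _apply_gain(lin: _Lineage, ev: PlannedEvent, params: SimParams,
                rng: np.random.Generator, gid_counter: list[int]) -> dict:
    slot = next(s for s in params.slots if s.name == ev.slot)
    src = lin.copy_at(ev.source_slot)
    if not src.functional:
        raise RetrotraceError(f"source copy at {ev.source_slot} is not functional")
    exs, ins = _copy_gene_parts(lin, src)
    exs, ins = _splice_out_introns(exs, ins, ev.introns_removed)
    gene_seq = _interleave(exs, ins)
    if ev.promoter_carryover:
        ps, pe = src.promoter
        prom = lin.chroms[src.chrom][ps:pe]
        if src.strand == "-":
            prom = revcomp(prom)
    else:
        prom = _rand_seq(rng, PROMOTER_LEN)

    if slot.host is not None:
        host = lin.gene_by_symbol(slot.host.symbol)
        n_intr = len(host.exons) - 1
        k = slot.host_intron_ordinal
        if not 1 <= k <= n_intr:
            raise RetrotraceError(f"host has no intron ordinal {k}")
        gi = k - 1 if host.strand == "+" else n_intr - k  # genomic index
        left = host.exons[gi][1]
        right = host.exons[gi + 1][0]
        pos = (left + right) // 2
        strand = host.strand if slot.host_orientation == "same" else \
            ("-" if host.strand == "+" else "+")
        chrom = slot.chrom
    else:
        a = lin.gene_by_symbol(slot.anchors[slot.insert_after][0])
        b = lin.gene_by_symbol(slot.anchors[slot.insert_after + 1][0])
        pos = (a.end + b.start) // 2
        strand, chrom = slot.insert_strand, slot.chrom

    insert, gene_off, prom_off = _focal_insert_seq(gene_seq, prom, strand)
    lin.insert(chrom, pos, insert)
    class _G:  # ad-hoc carrier for _exon_intervals
        exons, introns = exs, ins
    exon_ivs = _exon_intervals(_G, pos + gene_off, strand)
    prom_iv = (pos + prom_off, pos + prom_off + PROMOTER_LEN)
    cp = FocalCopy(ev.slot, chrom, strand, exon_ivs, prom_iv,
                   carried=ev.promoter_carryover)
    lin.copies.append(cp)
    gid_counter[0] += 1
    lin.genes.append(GeneRecord(f"hce{gid_counter[0]}", _FOCAL_SYMBOL, chrom,
                                strand, list(exon_ivs)))
    return {"source_slot": ev.source_slot, "dest_slot": ev.slot,
            "introns_removed": ev.introns_removed,
            "promoter_carried": ev.promoter_carryover}


def _apply_intron_loss(lin: _Lineage, ev: PlannedEvent) -> dict:
    cp = lin.copy_at(ev.slot)
    exs, ins = _copy_gene_parts(lin, cp)
    exs, ins = _splice_out_introns(exs, ins, ev.introns_removed)
    gene_seq = _interleave(exs, ins)
    if cp.strand == "-":
        gene_seq = revcomp(gene_seq)
    lo = min(s for s, _ in cp.exons)
    hi = max(e for _, e in cp.exons)
    lin.replace(cp.chrom, lo, hi, gene_seq)
    class _G:
        exons, introns = exs, ins
    cp.exons = _exon_intervals(_G, lo, cp.strand)
    for g in lin.genes:
        if g.chromosome == cp.chrom and g.symbol == _FOCAL_SYMBOL \
                and min(s for s, _ in g.exons) == lo:
            g.exons = list(cp.exons)
    return {"slot": ev.slot, "introns_removed": ev.introns_removed}


def _apply_decay(lin: _Lineage, ev: PlannedEvent, rng: np.random.Generator,
                 stage: str) -> dict:
    cp = lin.copy_at(ev.slot)
    exs, _ = _copy_gene_parts(lin, cp)
    cds = "".join(exs)
    lo = min(s for s, _ in cp.exons)
    hi = max(e for _, e in cp.exons)
    if stage == "erased":
        s0, e0 = cp.span
        lin.replace(cp.chrom, s0, e0, _rand_seq(rng, e0 - s0))
        cp.stage = "erased"
        cp.functional = False
        cp.promoter = None
        cp.exons = [(s0, e0)]
    else:
        frac = rng.uniform(0.4, 0.6) if stage == "fragment" else rng.uniform(0.10, 0.20)
        L = max(12, int(frac * len(cds)))
        start = int(rng.integers(0, len(cds) - L + 1))
        frag = list(cds[start:start + L])
        n_fs = 2 if stage == "fragment" else 1
        for p in sorted(rng.choice(np.arange(4, L - 4), size=n_fs, replace=False))[::-1]:
            del frag[p]
        frag_seq = "".join(frag)
        if cp.strand == "-":
            frag_seq = revcomp(frag_seq)
        lin.replace(cp.chrom, lo, hi, frag_seq)
        cp.stage = stage
        cp.functional = False
        cp.exons = [(lo, lo + len(frag_seq))]
    lin.genes = [g for g in lin.genes
                 if not (g.chromosome == cp.chrom and g.symbol == _FOCAL_SYMBOL
                         and g.start >= lo - 1 and g.start <= hi)]
    return {"slot": ev.slot, "stage": stage}


# --------------------------------------------------------------------------
# substitutions under purifying selection on functional copies

def _protected_positions(lin: "_Lineage", chrom: str) -> set[int]:
    prot: set[int] = set()
    for cp in lin.copies:
        if cp.chrom != chrom or not cp.functional:
            continue
        ivs = sorted(cp.exons)
        for i in range(len(ivs) - 1):  # splice dinucleotides
            a, b = ivs[i][1], ivs[i + 1][0]
            prot.update((a, a + 1, b - 2, b - 1))
        if cp.promoter and cp.carried:
            ps, pe = cp.promoter
            for off, L in lin.promoter_features:
                i0 = PROMOTER_LEN + off
                for k in range(L):
                    prot.add(ps + i0 + k if cp.strand == "+" else pe - 1 - (i0 + k))
    for g in lin.genes:  # host-gene splice sites stay splicable
        if g.chromosome != chrom or len(g.exons) < 2:
            continue
        for i in range(len(g.exons) - 1):
            a, b = g.exons[i][1], g.exons[i + 1][0]
            prot.update((a, a + 1, b - 2, b - 1))
    return prot


def _cds_index(cp: FocalCopy, chrom_pos: int) -> int | None:
    """Map a genomic position to its CDS index for a functional copy."""
    ivs = sorted(cp.exons)
    total = sum(e - s for s, e in ivs)
    acc = 0
    for s, e in ivs:
        if s <= chrom_pos < e:
            fwd = acc + (chrom_pos - s)
            return fwd if cp.strand == "+" else total - 1 - fwd
        acc += e - s
    return None


def _mutate(lin: _Lineage, rate: float, rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    comp = str.maketrans("ACGT", "TGCA")
    for chrom in sorted(lin.chroms):
        seq = lin.chroms[chrom]
        n = rng.binomial(len(seq), rate)
        if n == 0:
            continue
        positions = rng.choice(len(seq), size=n, replace=False)
        prot = _protected_positions(lin, chrom)
        s = list(seq)
        func_copies = [c for c in lin.copies if c.chrom == chrom and c.functional]
        for p in sorted(int(x) for x in positions):
            if p in prot:
                continue
            old = s[p]
            if old not in _BASES:
                continue
            new = _BASES[(_BASES.index(old) + int(rng.integers(1, 4))) % 4]
            veto = False
            for cp in func_copies:
                ci = _cds_index(cp, p)
                if ci is None:
                    continue
                if ci < 3 or ci >= sum(e - x for x, e in cp.exons) - 3:
                    veto = True  # start and stop codons are invariant
                    break
                base = new if cp.strand == "+" else new.translate(comp)
                cds = _current_cds(lin, cp)
                codon_i = ci // 3
                codon = list(cds[codon_i * 3:codon_i * 3 + 3])
                codon[ci % 3] = base
                if "".join(codon) in _STOPS:
                    veto = True  # nonsense substitutions are purged
                    break
            if not veto:
                s[p] = new
        lin.chroms[chrom] = "".join(s)


def _current_cds(lin: _Lineage, cp: FocalCopy) -> str:
    seq = lin.chroms[cp.chrom]
    ivs = sorted(cp.exons)
    cds = "".join(seq[s:e] for s, e in ivs)
    return revcomp(cds) if cp.strand == "-" else cds


# --------------------------------------------------------------------------
# the simulator proper

def simulate_clade(tree: SpeciesTree | str, params: SimParams,
                   ) -> SimResult:
    """Evolve a clade of genomes along ``tree`` under ``params``.

    Identical parameters (including the seed) give byte-identical output.
    Raises on an event referencing a branch absent from the tree.
    """
    if isinstance(tree, str):
        tree = read_newick(tree)
    if len(tree.leaves()) < 2:
        raise RetrotraceError("tree must have at least 2 leaves")
    known = set(tree.branch_ids())
    for ev in params.events:
        if ev.branch_id not in known or ev.branch_id == "ROOT":
            raise RetrotraceError(f"event references unknown branch {ev.branch_id!r}")
    params = replace(params, slots=params.slots or default_slots(
        n_neighbors=params.n_neighbor_genes))

    rng = np.random.default_rng(params.seed)
    anc = make_ancestral_he_gene(rng)
    root_lin = _ancestor(rng, params, anc)
    root_lin.promoter_features = [(anc.tata_offset, len(TATA)),
                                  (anc.klf_offset, len(KLF_SITE)),
                                  (anc.foxa3_offset, len(FOXA3_SITE))]

    by_branch: dict[str, list[PlannedEvent]] = {}
    for ev in params.events:
        by_branch.setdefault(ev.branch_id, []).append(ev)

    log: list[LogEntry] = []
    genomes: dict[str, AnnotatedGenome] = {}
    truth: dict[str, list[FocalCopy]] = {}
    gid_counter = [0]

    def walk(node, lin: _Lineage) -> None:
        if node is not tree.root:
            for ev in by_branch.get(node.branch_id, []):
                if ev.kind == "translocation_gain":
                    payload = _apply_gain(lin, ev, params, rng, gid_counter)
                    if ev.introns_removed > 0:
                        log.append(LogEntry(node.branch_id, "intron_loss",
                                            {"slot": ev.slot,
                                             "introns_removed": ev.introns_removed}))
                    log.append(LogEntry(node.branch_id, "translocation_gain", payload))
                elif ev.kind == "intron_loss":
                    log.append(LogEntry(node.branch_id, "intron_loss",
                                        _apply_intron_loss(lin, ev)))
                elif ev.kind == "pseudogenization":
                    log.append(LogEntry(node.branch_id, "pseudogenization",
                                        _apply_decay(lin, ev, rng, ev.stage)))
                elif ev.kind == "copy_loss":
                    log.append(LogEntry(node.branch_id, "copy_loss",
                                        _apply_decay(lin, ev, rng, "erased")))
                else:
                    raise RetrotraceError(f"unknown event kind {ev.kind!r}")
            _mutate(lin, params.subst_rate, rng)
        if node.is_leaf:
            genome = AnnotatedGenome(node.label, dict(lin.chroms),
                                     _copy.deepcopy(lin.genes))
            genome.validate()
            genomes[node.label] = genome
            truth[node.label] = _copy.deepcopy(lin.copies)
        else:
            for child in node.children:
                walk(child, lin.clone())

    walk(tree.root, root_lin)
    return SimResult(tree, genomes, log, truth, anc, params)


# --------------------------------------------------------------------------
# the worked-example clade

FIXTURE_NEWICK = (
    "(arowana,(eel,((herring,((zebrafish,cavefish),catfish)),"
    "(salmon,(((croaker,(seabass,stickleback)),(tilapia,cichlid)),"
    "(medaka,(tonguesole,(takifugu,tetraodon))))))));"
)

_BASAL = ["arowana", "eel", "herring"]
_OTO = ["catfish", "cavefish", "zebrafish"]
_EU = ["cichlid", "croaker", "medaka", "salmon", "seabass", "stickleback",
       "takifugu", "tetraodon", "tilapia", "tonguesole"]


def _bid(labels) -> str:
    return ",".join(sorted(labels))


def fixture_slots() -> list[SlotSpec]:
    return [
        # ancestral teleost slot: tgfb2l(+) … focal … kcnk4(-), tail-to-tail
        SlotSpec("tgfb2l", "chr_anc", [("tgfb2l", "+"), ("kcnk4", "-")],
                 insert_after=0, insert_strand="+"),
        # otophysan destination: inside intron 14 of an aox5-like host
        SlotSpec("aox5", "chr_oto", [("dgkh", "+"), ("spata5", "-")],
                 host=HostSpec("aox5", 16), host_intron_ordinal=14,
                 host_orientation="opposite"),
        # euteleostean parent slot
        SlotSpec("glo1", "chr_eu", [("glo1", "+"), ("slco3a1", "-"), ("mctp2b", "+")],
                 insert_after=0, insert_strand="+"),
        # the four daughter slots
        SlotSpec("anxa2a", "chr_d1", [("anxa2a", "+"), ("roraa", "+"), ("otud7a", "-")],
                 insert_after=1, insert_strand="+"),
        SlotSpec("glrx5", "chr_d2", [("glrx5", "+"), ("prkrip1", "-"), ("serpina1l", "+")],
                 insert_after=1, insert_strand="-"),
        SlotSpec("adgra1a", "chr_d3", [("adgra1a", "-"), ("acbd4", "+"), ("llgl2", "+")],
                 insert_after=1, insert_strand="+"),
        SlotSpec("fer1l4", "chr_d4", [("fer1l4", "+"), ("cpne1", "+"), ("nfs1", "-")],
                 insert_after=1, insert_strand="+"),
    ]


def fixture_events() -> list[PlannedEvent]:
    b_oto = _bid(_OTO)
    b_eu = _bid(_EU)
    ev = [
        # otophysan stem: retrocopy with 3 introns lost, into the aox5 host
        PlannedEvent(b_oto, "translocation_gain", "aox5", source_slot="tgfb2l",
                     introns_removed=3, promoter_carryover=True),
        PlannedEvent(b_oto, "copy_loss", "tgfb2l"),
        # euteleostean stem: fully processed retrocopy into the glo1 region
        PlannedEvent(b_eu, "translocation_gain", "glo1", source_slot="tgfb2l",
                     introns_removed=8, promoter_carryover=True),
        PlannedEvent(b_eu, "copy_loss", "tgfb2l"),
        # four independent duplicative translocations within euteleostei
        PlannedEvent("salmon", "translocation_gain", "anxa2a",
                     source_slot="glo1", introns_removed=0),
        PlannedEvent(_bid(["croaker", "seabass", "stickleback"]),
                     "translocation_gain", "adgra1a", source_slot="glo1"),
        PlannedEvent(_bid(["tilapia", "cichlid"]),
                     "translocation_gain", "glrx5", source_slot="glo1"),
        PlannedEvent(_bid(["takifugu", "tetraodon"]),
                     "translocation_gain", "fer1l4", source_slot="glo1"),
        # graded decay of the euteleostean parent-slot copy
        PlannedEvent(_bid(["seabass", "stickleback"]), "pseudogenization",
                     "glo1", stage="fragment"),
        PlannedEvent("tilapia", "pseudogenization", "glo1", stage="short"),
        PlannedEvent("cichlid", "copy_loss", "glo1"),
        PlannedEvent(_bid(["takifugu", "tetraodon"]), "copy_loss", "glo1"),
    ]
    return ev


def emit_fixture_paper_clade(seed: int = 42, subst_rate: float = 0.002) -> SimResult:
    """Deterministic 16-leaf clade reproducing the qualitative event history
    of the focal family: two promoter-carrying retrocopy translocations on
    the otophysan and euteleostean stems (with 3 and 8 introns lost), four
    further duplicative translocations within euteleostei, and graded
    parent-slot vestiges."""
    params = SimParams(seed=seed, subst_rate=subst_rate, slots=fixture_slots(),
                       parent_slot="tgfb2l", events=fixture_events())
    return simulate_clade(read_newick(FIXTURE_NEWICK), params)


# --------------------------------------------------------------------------
# random planted scenarios (recovery benchmarks)

SCENARIO_NEWICK = "((A,(B,C)),((D,E),(F,(G,H))));"


def random_scenario(scenario_seed: int, subst_rate: float = 0.0) -> SimParams:
    """Draw a random planted-event scenario on the 8-leaf benchmark tree.

    Gains are planted on disjoint (non-nested) branches so every intron-loss
    magnitude is identifiable at the tips; erasures never disconnect a gain
    clade from its stem.  The returned params are a pure function of the
    scenario seed.
    """
    rng = np.random.default_rng(scenario_seed)
    tree = read_newick(SCENARIO_NEWICK)
    internal = [n.branch_id for n in tree.postorder()
                if not n.is_leaf and n is not tree.root]
    events: list[PlannedEvent] = []
    n_gains = int(rng.integers(1, 3))
    rng.shuffle(internal)
    used: list[str] = []
    dest_i = 0
    for b in internal:
        if len(used) >= n_gains:
            break
        if any(tree.is_strict_descendant(b, u) or tree.is_strict_descendant(u, b)
               or u == b for u in used):
            continue
        # sibling gain branches are not identifiable: two equal losses on
        # sisters reconstruct as one earlier shared loss under parsimony
        if any(tree.node(u).parent is tree.node(b).parent for u in used):
            continue
        used.append(b)
        events.append(PlannedEvent(
            b, "translocation_gain", f"dest{dest_i}", source_slot="parent",
            introns_removed=int(rng.integers(1, 9)),
            promoter_carryover=bool(rng.integers(0, 2))))
        # optional decay of the source (parent-slot) copy in one descendant of
        # the gain — duplication followed by pseudogenization of the source.
        # Victims never share a cherry, so each decay is a distinct event.
        if rng.random() < 0.5:
            leaves = sorted(tree.leaves_under(b))
            victim = leaves[int(rng.integers(0, len(leaves)))]
            victim_parent = tree.node(victim).parent
            taken = {e.branch_id for e in events
                     if e.kind == "pseudogenization" and e.slot == "parent"}
            siblings = {c.branch_id for c in victim_parent.children}
            if not (siblings & taken):
                stage = ["fragment", "short"][int(rng.integers(0, 2))]
                events.append(PlannedEvent(victim, "pseudogenization",
                                           "parent", stage=stage))
        dest_i += 1
    return SimParams(seed=int(rng.integers(0, 2**31 - 1)), subst_rate=subst_rate,
                     slots=default_slots(n_dest=max(dest_i, 1)),
                     events=events)


# --------------------------------------------------------------------------
# on-disk outputs

def write_outputs(result: SimResult, outdir) -> None:
    """FASTA + GFF3 per species, the Newick tree, and the ground-truth event
    log as TSV."""
    import os

    from .core_io import write_fasta, write_gff3, write_newick
    os.makedirs(outdir, exist_ok=True)
    for sp, genome in sorted(result.genomes.items()):
        write_fasta(genome.chromosomes, os.path.join(outdir, f"{sp}.fa"))
        write_gff3(genome, os.path.join(outdir, f"{sp}.gff3"))
    write_newick(result.tree, os.path.join(outdir, "species.nwk"))
    with open(os.path.join(outdir, "events.tsv"), "w") as fh:
        fh.write("branch_id\tkind\tpayload\n")
        for e in result.event_log:
            payload = ";".join(f"{k}={v}" for k, v in sorted(e.payload.items()))
            fh.write(f"{e.branch_id}\t{e.kind}\t{payload}\n")
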