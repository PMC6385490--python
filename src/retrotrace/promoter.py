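"""Promoter architecture and carry-over analysis.

Offsets are negative coordinates relative to the transcription start site
(TSS, the first base of exon 1 in the gene's sense): the window base
immediately 5' of the TSS has offset −1.  The diagnostic architecture is a
TATA box close to the TSS plus klf3/17 (``CWCCC``) and foxa3
(``TGTTTRCWYW``) binding sites inside the indispensable −192…−91 subregion;
a translocated copy is scored as promoter-carrying when that architecture
sits inside a block conserved against a reference upstream region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import skbio

from .core_io import AnnotatedGenome, RetrotraceError, match_iupac, revcomp
from .genemodel import GeneModel

logger = logging.getLogger(__name__)

KLF_PATTERN = "CWCCC"          # CACCC or CTCCC
FOXA3_PATTERN = "TGTTTRCWYW"   # TGTTT(A/G)C(T/A)(T/C)(A/T)
TATA_PATTERN = "TATAWAW"
TATA_WINDOW = (-50, -20)
INDISPENSABLE = (-192, -91)
DEFAULT_WINDOW = 200


@dataclass
class UpstreamSeq:
    seq: str
    truncated: bool

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PromoterReport:
    species_id: str
    slot: str
    upstream_seq: str
    truncated: bool
    tata_position: int | None
    klf_hits: list[tuple[int, str]]
    foxa3_hits: list[tuple[int, str]]
    conserved_block: tuple[int, int] | None = None
    carryover: bool | None = None
    evidence: dict = field(default_factory=dict)


@dataclass
class UpstreamTree:
    tree: skbio.TreeNode
    newick: str
    method: str = "nj+jukes-cantor"
    excluded: list[str] = field(default_factory=list)


def extract_upstream(genome: AnnotatedGenome, gene: GeneModel,
                     window: int = DEFAULT_WINDOW) -> UpstreamSeq:
    """The ``window`` bases immediately 5' of the TSS, in the gene's sense.

    Truncated (and flagged) at chromosome ends.  Raises on window ≤ 0.
    """
    if window <= 0:
        raise RetrotraceError("window must be positive")
    seq = genome.chromosomes[gene.chromosome]
    if gene.strand == "+":
        tss = gene.exons[0][0]
        lo = max(0, tss - window)
        return UpstreamSeq(seq[lo:tss], truncated=tss - window < 0)
    tss = gene.exons[-1][1]
    hi = min(len(seq), tss + window)
    return UpstreamSeq(revcomp(seq[tss:hi]), truncated=tss + window > len(seq))


def _offset_hits(pattern: str, upstream: str) -> list[tuple[int, str]]:
    L = len(upstream)
    return [(i - L, upstream[i:i + len(pattern)])
            for i in match_iupac(pattern, upstream)]


def find_tata(upstream_seq: str, search_window: tuple[int, int] = TATA_WINDOW,
              ) -> int | None:
    """Offset of the 3'-most TATA-box match starting inside the window."""
    lo, hi = search_window
    hits = [off for off, _ in _offset_hits(TATA_PATTERN, upstream_seq)
            if lo <= off <= hi]
    return max(hits) if hits else None


def scan_tf_sites(upstream_seq: str) -> tuple[list[tuple[int, str]],
                                              list[tuple[int, str]]]:
    """klf3/17 and foxa3 site hits as (offset, matched string); sense strand."""
    return (_offset_hits(KLF_PATTERN, upstream_seq),
            _offset_hits(FOXA3_PATTERN, upstream_seq))


def make_report(genome: AnnotatedGenome, gene: GeneModel, slot: str = "",
                window: int = DEFAULT_WINDOW) -> PromoterReport:
    up = extract_upstream(genome, gene, window)
    klf, foxa = scan_tf_sites(up.seq)
    return PromoterReport(genome.species_id, slot, up.seq, up.truncated,
                          find_tata(up.seq), klf, foxa)


# --------------------------------------------------------------------------
# conserved block

def conserved_block(upstream_seqs: list[str], min_identity: float = 0.7,
                    min_length: int = 100) -> tuple[int, int] | None:
    """Longest TSS-anchored window conserved across all sequences.

    Sequences are aligned at their 3' ends (the TSS); the block is the
    longest window whose identity is ≥ ``min_identity`` for **every** pair,
    as offsets [start, end) relative to the TSS.  Returns None when no
    window of at least ``min_length`` qualifies.
    """
    if len(upstream_seqs) < 2:
        raise RetrotraceError("need at least 2 sequences")
    L = min(len(s) for s in upstream_seqs)
    if L < min_length:
        return None
    tails = [s[len(s) - L:].upper() for s in upstream_seqs]
    arrs = [np.frombuffer(t.encode(), dtype=np.uint8) for t in tails]
    # cumulative mismatch counts per pair
    cums = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            mm = (arrs[i] != arrs[j]).astype(np.int32)
            cums.append(np.concatenate([[0], np.cumsum(mm)]))
    cums = np.asarray(cums)  # (pairs, L+1)
    best = None
    for length in range(L, min_length - 1, -1):
        starts = np.arange(0, L - length + 1)
        mism = cums[:, starts + length] - cums[:, starts]  # (pairs, starts)
        ok = (mism <= (1 - min_identity) * length).all(axis=0)
        idx = np.flatnonzero(ok)
        if idx.size:
            a = int(starts[idx[0]])  # leftmost on ties
            best = (a - L, a + length - L)
            break
    return best


def classify_carryover(parent_report: PromoterReport,
                       daughter_report: PromoterReport,
                       min_identity: float = 0.7, min_length: int = 100,
                       ) -> tuple[bool, dict]:
    """Did the translocated copy carry its promoter along?

    True iff the daughter upstream region shares a conserved block with the
    reference (parent-slot or cross-species) upstream region and that block
    contains a TATA box plus at least one klf and one foxa3 site inside the
    indispensable subregion.  The evidence dict lists the qualifying motif
    offsets and names any missing component.
    """
    block = conserved_block([parent_report.upstream_seq,
                             daughter_report.upstream_seq],
                            min_identity, min_length)
    evidence: dict = {"conserved_block": block}
    if block is None:
        evidence["missing"] = ["conserved_block"]
        return False, evidence
    b_lo, b_hi = block
    i_lo, i_hi = INDISPENSABLE

    def inside(off: int, pat_len: int) -> bool:
        return b_lo <= off and off + pat_len <= b_hi and \
            i_lo <= off and off + pat_len <= i_hi + 1

    tata = daughter_report.tata_position
    tata_ok = tata is not None and b_lo <= tata and tata + len(TATA_PATTERN) <= b_hi
    klf = [off for off, _ in daughter_report.klf_hits if inside(off, len(KLF_PATTERN))]
    foxa = [off for off, _ in daughter_report.foxa3_hits
            if inside(off, len(FOXA3_PATTERN))]
    evidence.update({"tata": tata if tata_ok else None,
                     "klf_offsets": klf, "foxa3_offsets": foxa})
    missing = [name for name, ok in
               (("tata", tata_ok), ("klf", bool(klf)), ("foxa3", bool(foxa)))
               if not ok]
    if missing:
        evidence["missing"] = missing
        return False, evidence
    return True, evidence


# --------------------------------------------------------------------------
# upstream-region distance tree

def _jc_distance(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    p = sum(x != y for x, y in zip(a[:n], b[:n])) / n
    p = min(p, 0.74)  # JC correction diverges at 3/4
    return -0.75 * np.log(1 - 4 * p / 3) if p > 0 else 0.0


def upstream_tree(upstream_seqs: dict[str, str], tata_offsets: dict[str, int | None],
                  region_length: int = 100) -> UpstreamTree:
    """Neighbor-joining tree of the regions ~100 bp 5' of each TATA box.

    Species lacking a TATA box are excluded with a warning; fewer than three
    usable sequences raise.  Distances are Jukes–Cantor corrected
    p-distances; no indels are modeled, so sequences are compared
    positionally from the TATA box outward.
    """
    regions: dict[str, str] = {}
    excluded: list[str] = []
    for sp, seq in sorted(upstream_seqs.items()):
        off = tata_offsets.get(sp)
        if off is None:
            logger.warning("species %s lacks a TATA box; excluded from tree", sp)
            excluded.append(sp)
            continue
        idx = len(seq) + off
        regions[sp] = seq[max(0, idx - region_length):idx]
    if len(regions) < 3:
        raise RetrotraceError("need ≥3 sequences with a TATA box")
    names = sorted(regions)
    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _jc_distance(regions[names[i]], regions[names[j]])
    tree = skbio.tree.nj(skbio.DistanceMatrix(dm, ids=names))
    return UpstreamTree(tree, str(tree).strip(), excluded=excluded)
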