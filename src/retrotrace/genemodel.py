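"""In-silico cloning: exon–intron structure from CDS vs genomic sequence.

The central operation maps a coding sequence onto a genomic region under the
GT-AG rule: exons are gapless, near-exact matches; the gaps between them must
begin ``GT`` and end ``AG`` and be at least ``min_intron`` long.  Among all
valid splice chains the mapper returns the one with the fewest introns, then
the fewest mismatches, then the smallest total donor coordinate (a
deterministic "leftmost donor" rule).  This mirrors how gene structures are
determined by hand when cloning genes in silico from assemblies, but with an
explicit, reproducible objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from Bio import Align

from .core_io import AnnotatedGenome, RetrotraceError, revcomp, match_iupac

# lexicographic objective: mismatches, then intron count, then total donor
# coordinate (leftmost-donor tie-break).  Minimizing mismatches first is safe
# for single-copy loci — realigning part of the CDS elsewhere via an extra
# intron lands on unrelated sequence (~75% mismatched) — and on clean data it
# reduces to the minimum-intron-count chain of exact segments.
_W_MISMATCH = 1 << 45
_W_INTRON = 1 << 25
_INF = np.iinfo(np.int64).max // 4

#: astacin-family active-site consensus patterns (amino acids, x = any)
ACTIVE_SITE_PATTERNS = ("HEXXHXXGFXHEXXRXDR", "SXMHY")


class UnmappableError(RetrotraceError):
    """No splice chain covers the CDS within the mismatch tolerance."""


class SpliceViolationError(RetrotraceError):
    """A chain exists, but only with gaps that are not GT..AG introns."""


@dataclass
class GeneModel:
    """One gene's exon–intron structure on a genomic sequence."""

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, ascending genomic order
    cds: str
    host_insertion: tuple[str, int, str] | None = None  # (host symbol, 1-based intron ordinal, 'same'|'opposite')

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0])
                for i in range(len(self.exons) - 1)]


@dataclass
class VestigeState:
    """Graded remnant of a gene at a locus: full → fragment → short → absent."""

    state: str  # full | fragment | short_fragment | absent
    coverage: float  # fraction of reference CDS aligned
    disruption: int  # frameshifts + premature stops
    span: tuple[int, int] | None = None  # aligned subinterval of the locus sequence

    _ORDER = ("absent", "short_fragment", "fragment", "full")

    def rank(self) -> int:
        return self._ORDER.index(self.state)


# --------------------------------------------------------------------------
# splice-aware CDS → genome mapping

def _splice_dp(cds: str, region: str, min_intron: int, require_gt_ag: bool):
    """Fewest-introns DP.  Returns (exons, mismatch positions) in region
    coordinates or None when no full-coverage chain exists."""
    n, m = len(cds), len(region)
    if n == 0 or m < n:
        return None
    reg = np.frombuffer(region.encode(), dtype=np.uint8)
    cdsb = np.frombuffer(cds.encode(), dtype=np.uint8)

    if require_gt_ag:
        donors = np.flatnonzero((reg[:-1] == ord("G")) & (reg[1:] == ord("T")))
        acc = np.zeros(m + 1, dtype=bool)  # acc[j]: intron may end at region j-1
        if m >= 3:
            ag = (reg[:-1] == ord("A")) & (reg[1:] == ord("G"))
            acc[3:] = ag[: m - 2]
    else:
        donors = np.arange(1, m, dtype=np.int64)
        acc = np.ones(m + 1, dtype=bool)
        acc[:3] = False
    donors = donors[donors >= 1]  # previous exon needs >= 1 base before donor

    prev = np.full(m + 1, _INF, dtype=np.int64)
    use_intron = np.zeros((n + 1, m + 1), dtype=bool)
    donor_of = np.zeros((n + 1, m + 1), dtype=np.int32)

    js = np.arange(m + 1)
    # acceptor position j admits donors d <= j-1-min_intron
    max_d = js - 1 - min_intron
    n_avail = np.searchsorted(donors, max_d, side="right")

    for i in range(1, n + 1):
        mmvec = (reg != cdsb[i - 1]).astype(np.int64) * _W_MISMATCH
        cur = np.full(m + 1, _INF, dtype=np.int64)
        if i == 1:
            cur[1:] = mmvec
        else:
            cur[1:] = np.where(prev[:-1] < _INF, prev[:-1] + mmvec, _INF)
            if donors.size:
                dv = prev[donors]
                vals = np.where(dv < _INF, dv + donors, _INF)  # + donor coordinate
                pref = np.minimum.accumulate(vals)
                # strict-< running argmin keeps the leftmost donor on ties
                improved = np.empty(vals.size, dtype=bool)
                improved[0] = True
                improved[1:] = vals[1:] < pref[:-1]
                arg = np.maximum.accumulate(np.where(improved, np.arange(vals.size), -1))
                ok = acc & (n_avail > 0)
                idx = np.flatnonzero(ok)
                if idx.size:
                    t = n_avail[idx] - 1
                    cand = pref[t] + _W_INTRON
                    cand = np.where(pref[t] < _INF, cand + mmvec[idx - 1], _INF)
                    better = cand < cur[idx]
                    upd = idx[better]
                    cur[upd] = cand[better]
                    use_intron[i, upd] = True
                    donor_of[i, upd] = donors[arg[t[better]]]
        prev = cur

    ends = prev[1:]
    if not (ends < _INF).any():
        return None
    j_end = int(np.argmin(ends)) + 1  # ties -> leftmost end
    # backtrack
    exons: list[tuple[int, int]] = []
    i, j = n, j_end
    exon_end = j
    mismatches: list[int] = []
    while i >= 1:
        if region[j - 1] != cds[i - 1]:
            mismatches.append(j - 1)
        if i == 1:
            exons.append((j - 1, exon_end))
            break
        if use_intron[i, j]:
            d = int(donor_of[i, j])
            exons.append((j - 1, exon_end))
            exon_end = d
            j = d
        else:
            j -= 1
        i -= 1
    exons.reverse()
    return exons, sorted(mismatches)


def infer_gene_structure(cds: str, genomic_region: str, strand: str = "+",
                         min_intron: int = 40, max_mismatch_frac: float = 0.05,
                         gene_id: str = "gene", chromosome: str = "region",
                         ) -> GeneModel:
    """Determine the exon–intron structure of ``cds`` within a genomic region.

    Returns the minimum-intron-count chain of near-exact CDS segments whose
    gaps are GT..AG introns of length ≥ ``min_intron``.  Exon coordinates are
    relative to ``genomic_region`` (plus strand).  Raises
    :class:`UnmappableError` if no chain covers the CDS within the per-exon
    mismatch tolerance, :class:`SpliceViolationError` if a chain exists only
    with non-GT-AG gaps.
    """
    cds = cds.upper()
    if len(cds) < 30:
        raise RetrotraceError("CDS shorter than 30 nt")
    work = genomic_region.upper() if strand == "+" else revcomp(genomic_region.upper())

    def within_tolerance(res) -> bool:
        if res is None:
            return False
        exons, mismatches = res
        mm = np.asarray(mismatches)
        return all((int(((mm >= s) & (mm < e)).sum()) if mm.size else 0)
                   <= max_mismatch_frac * (e - s) for s, e in exons)

    res = _splice_dp(cds, work, min_intron, require_gt_ag=True)
    if not within_tolerance(res):
        relaxed = _splice_dp(cds, work, min_intron, require_gt_ag=False)
        if within_tolerance(relaxed):
            raise SpliceViolationError("chain requires a non-GT-AG gap")
        raise UnmappableError("no splice chain covers the CDS within tolerance")
    exons, mismatches = res
    if strand == "-":
        L = len(work)
        exons = sorted((L - e, L - s) for s, e in exons)
    return GeneModel(gene_id, chromosome, strand, exons, cds)


# --------------------------------------------------------------------------
# cross-species cloning

_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "local"
_ALIGNER.match_score = 1
_ALIGNER.mismatch_score = -3
_ALIGNER.open_gap_score = -5
_ALIGNER.extend_gap_score = -2


def _exon_hits(exon: str, chrom_seq: str, max_frac: float = 0.3,
               max_hits: int = 12) -> list[tuple[int, int, int]]:
    """Non-overlapping infix hits of one exon on one strand: (start, end, dist)."""
    hits = []
    masked = chrom_seq
    limit = int(max_frac * len(exon))
    for _ in range(max_hits):
        res = edlib.align(exon, masked, mode="HW", task="locations", k=limit)
        if res["editDistance"] < 0 or not res["locations"]:
            break
        s, e = res["locations"][0]
        e += 1
        hits.append((s, e, res["editDistance"]))
        masked = masked[:s] + "N" * (e - s) + masked[e:]
    return sorted(hits)


def find_family_loci(genome: AnnotatedGenome, seed_exons: list[str],
                     cluster_gap: int = 5000, pad: int = 400,
                     ) -> list[tuple[str, str, int, int]]:
    """Candidate loci of the gene family: (chromosome, strand, start, end).

    Each seed exon is searched on both strands of every chromosome; hits on
    the same chromosome/strand within ``cluster_gap`` of each other are merged
    into one candidate locus, padded by ``pad``.
    """
    raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for chrom, seq in genome.chromosomes.items():
        rc = revcomp(seq)
        for exon in seed_exons:
            if len(exon) < 20:
                continue
            for s, e, _ in _exon_hits(exon, seq):
                raw.setdefault((chrom, "+"), []).append((s, e))
            for s, e, _ in _exon_hits(exon, rc):
                raw.setdefault((chrom, "-"), []).append((len(seq) - e, len(seq) - s))
    loci = []
    for (chrom, strand), ivs in raw.items():
        ivs.sort()
        cs, ce = ivs[0]
        merged = []
        for s, e in ivs[1:]:
            if s <= ce + cluster_gap:
                ce = max(ce, e)
            else:
                merged.append((cs, ce))
                cs, ce = s, e
        merged.append((cs, ce))
        L = len(genome.chromosomes[chrom])
        for s, e in merged:
            loci.append((chrom, strand, max(0, s - pad), min(L, e + pad)))
    return sorted(loci)


def cross_species_clone(seed_exons: list[str], target_genome: AnnotatedGenome,
                        min_intron: int = 40, max_mismatch_frac: float = 0.05,
                        ) -> list[tuple[tuple[str, str, int, int], GeneModel | VestigeState]]:
    """Clone a family in a related species from seed exon sequences.

    Returns one entry per candidate locus: the locus interval and either a
    :class:`GeneModel` (all exons map collinearly with GT-AG gaps) or the
    :class:`VestigeState` of the best partial hit.  Absence of any locus is a
    valid result (empty list).
    """
    seed_cds = "".join(seed_exons)
    out = []
    for chrom, strand, s, e in find_family_loci(target_genome, seed_exons):
        window = target_genome.chromosomes[chrom][s:e]
        try:
            gm = infer_gene_structure(seed_cds, window, strand,
                                      min_intron=min_intron,
                                      max_mismatch_frac=max_mismatch_frac,
                                      chromosome=chrom)
            gm.exons = [(x + s, y + s) for x, y in gm.exons]
            gm.cds = _spliced(target_genome, gm)
            out.append(((chrom, strand, s, e), gm))
        except RetrotraceError:
            out.append(((chrom, strand, s, e), classify_vestige(window, seed_cds)))
    return out


def _spliced(genome: AnnotatedGenome, gm: GeneModel) -> str:
    seq = genome.chromosomes[gm.chromosome]
    cds = "".join(seq[a:b] for a, b in gm.exons)
    return revcomp(cds) if gm.strand == "-" else cds


# --------------------------------------------------------------------------
# protein diagnostics

def scan_protein_diagnostics(protein: str) -> tuple[int, list[int], int]:
    """Count astacin active-site consensus hits and cysteines.

    Returns (number of non-overlapping hits of the two consensus patterns,
    their start positions, total cysteine count).  Raises ``ValueError`` on a
    residue outside the 20-letter alphabet.
    """
    prot = protein.upper()
    bad = set(prot) - set(IUPAC_OK_AA)
    if bad:
        raise ValueError(f"illegal residues: {sorted(bad)}")
    positions: list[int] = []
    for pat in ACTIVE_SITE_PATTERNS:
        hits = match_iupac(pat, prot, alphabet="aa")
        # non-overlapping, left to right
        last_end = -1
        for h in hits:
            if h >= last_end:
                positions.append(h)
                last_end = h + len(pat)
    return len(positions), sorted(positions), prot.count("C")


IUPAC_OK_AA = "ACDEFGHIKLMNPQRSTVWY"


# --------------------------------------------------------------------------
# vestige classification

def classify_vestige(locus_sequence: str, reference_cds: str) -> VestigeState:
    """Grade a locus occupant against the reference CDS.

    Coverage is the reference fraction spanned by the best local alignment
    (both strands tried); disruption counts frameshifting indels plus
    premature stop codons in the reference reading frame.  Thresholds:
    full ≥ 0.9 coverage with no disruption; fragment 0.2–0.9;
    short_fragment 0.05–0.2; absent < 0.05.
    """
    ref = reference_cds.upper()
    if not ref:
        raise RetrotraceError("empty reference CDS")
    locus = locus_sequence.upper()
    best, best_rc = None, False
    for rc, cand in ((False, locus), (True, revcomp(locus))):
        if not cand:
            continue
        alns = _ALIGNER.align(ref, cand)
        if len(alns) == 0:
            continue
        a = alns[0]
        if best is None or a.score > best.score:
            best, best_rc = a, rc
    if best is None or best.score <= 0:
        return VestigeState("absent", 0.0, 0)
    ra, qa = best.aligned  # blocks in reference / locus coordinates
    q_lo, q_hi = qa[0][0], qa[-1][1]
    if best_rc:
        q_lo, q_hi = len(locus) - q_hi, len(locus) - q_lo
    ref_span = ra[-1][1] - ra[0][0]
    coverage = ref_span / len(ref)
    disruption = _count_disruption(best, ref)
    if coverage >= 0.9 and disruption == 0:
        state = "full"
    elif coverage >= 0.2:
        state = "fragment"
    elif coverage >= 0.05:
        state = "short_fragment"
    else:
        state = "absent"
    return VestigeState(state, round(coverage, 4), disruption, (int(q_lo), int(q_hi)))


def _count_disruption(alignment, ref: str) -> int:
    ra, qa = alignment.aligned
    frameshifts = 0
    for k in range(1, len(ra)):
        ref_gap = ra[k][0] - ra[k - 1][1]
        q_gap = qa[k][0] - qa[k - 1][1]
        if (ref_gap - q_gap) % 3 != 0:
            frameshifts += 1
    # premature stops: translate the locus in the frame set by the reference
    target = str(alignment.target)  # reference
    query = str(alignment.query)
    stops = 0
    for (rs, re_), (qs, qe) in zip(ra, qa):
        phase = rs % 3
        off = (3 - phase) % 3
        seg = query[qs + off: qe]
        for p in range(0, len(seg) - 2, 3):
            codon = seg[p:p + 3]
            if codon in ("TAA", "TAG", "TGA"):
                # the reference's own terminal stop is not a disruption
                ref_pos = rs + off + p
                if ref_pos < len(ref) - 3:
                    stops += 1
    return frameshifts + stops
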