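import numpy as np
import pytest

from retrotrace.core_io import AnnotatedGenome, RetrotraceError, revcomp
from retrotrace.genemodel import GeneModel
from retrotrace.promoter import (classify_carryover, conserved_block,
                                 extract_upstream, find_tata, make_report,
                                 scan_tf_sites, upstream_tree)
from retrotrace.synthdata import PlannedEvent, SimParams, default_slots, simulate_clade
from oracles import iupac_expand_match


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _genome(seq, species="sp"):
    return AnnotatedGenome(species, {"chr": seq})


def _gene(strand, exons):
    return GeneModel("g", "chr", strand, exons, "")


# --------------------------------------------------------------------------
# extract_upstream

def test_plus_strand_window_coordinates():
    rng = np.random.default_rng(1)
    seq = _rand(rng, 900)
    up = extract_upstream(_genome(seq), _gene("+", [(500, 700)]), window=192)
    assert up.seq == seq[308:500]
    assert not up.truncated


def test_minus_strand_upstream_is_reverse_complement():
    seq = "ACGTACGTACGTACGTACGT"  # gene at [4,10) on '-': upstream is [10,16) rc
    up = extract_upstream(_genome(seq), _gene("-", [(4, 10)]), window=6)
    assert up.seq == revcomp(seq[10:16])


def test_truncation_at_chromosome_start():
    rng = np.random.default_rng(2)
    seq = _rand(rng, 400)
    up = extract_upstream(_genome(seq), _gene("+", [(10, 200)]), window=200)
    assert up.seq == seq[:10]
    assert up.truncated


def test_nonpositive_window_rejected():
    with pytest.raises(RetrotraceError):
        extract_upstream(_genome("ACGT" * 100), _gene("+", [(100, 200)]), 0)


def test_strand_mirror_symmetry():
    """A gene and its mirror image on the reverse-complemented chromosome
    yield the same upstream sequence."""
    rng = np.random.default_rng(3)
    seq = _rand(rng, 600)
    gene = _gene("+", [(300, 400), (450, 520)])
    up1 = extract_upstream(_genome(seq), gene, 150)
    L = len(seq)
    mirrored = _gene("-", sorted((L - e, L - s) for s, e in gene.exons))
    up2 = extract_upstream(_genome(revcomp(seq)), mirrored, 150)
    assert up1.seq == up2.seq


# --------------------------------------------------------------------------
# TATA and TF sites

def _with_site(site, offset, length=200, seed=4):
    rng = np.random.default_rng(seed)
    s = list("".join("AC"[i] for i in rng.integers(0, 2, size=length)))
    i = length + offset
    s[i:i + len(site)] = site
    return "".join(s)


def test_tata_found_at_planted_offset():
    assert find_tata(_with_site("TATAAAT", -31)) == -31


def test_no_tata_returns_none():
    assert find_tata("AC" * 100) is None


def test_three_prime_most_tata_wins():
    seq = _with_site("TATAAAT", -45)
    seq = seq[:200 - 28] + "TATATAT" + seq[200 - 21:]
    # naive scan oracle: all window matches, take the largest offset
    oracle = max(off for off in range(-50, -19)
                 if iupac_expand_match("TATAWAW", seq[200 + off:200 + off + 7])
                 == [0])
    assert find_tata(seq) == oracle == -28


def test_both_klf_variants_counted():
    seq = "TT" + "CACCC" + "GG" + "CTCCC" + "TT"
    klf, foxa = scan_tf_sites(seq)
    assert len(klf) == 2
    assert [m for _, m in klf] == ["CACCC", "CTCCC"]


def test_foxa3_example_hit():
    klf, foxa = scan_tf_sites("TGTTTGCATT")
    assert len(foxa) == 1
    assert foxa[0] == (-10, "TGTTTGCATT")


def test_no_foxa3_without_g_or_t():
    rng = np.random.default_rng(6)
    seq = "".join("AC"[i] for i in rng.integers(0, 2, size=100))
    _, foxa = scan_tf_sites(seq)
    assert foxa == []


def test_scanner_equals_expansion_oracle():
    rng = np.random.default_rng(7)
    for _ in range(10):
        seq = _rand(rng, 300)
        klf, foxa = scan_tf_sites(seq)
        assert [o + len(seq) for o, _ in klf] == iupac_expand_match("CWCCC", seq)
        assert [o + len(seq) for o, _ in foxa] == \
            iupac_expand_match("TGTTTRCWYW", seq)


# --------------------------------------------------------------------------
# conserved block

def test_identical_sequences_full_window():
    rng = np.random.default_rng(8)
    s = _rand(rng, 200)
    assert conserved_block([s, s, s]) == (-200, 0)


def test_unrelated_sequences_no_block():
    rng = np.random.default_rng(9)
    assert conserved_block([_rand(rng, 200) for _ in range(3)]) is None


def test_carried_promoters_share_long_block_with_motifs():
    ev = PlannedEvent("A,B", "translocation_gain", "dest0",
                      source_slot="parent", introns_removed=8,
                      promoter_carryover=True)
    params = SimParams(seed=12, subst_rate=0.005, slots=default_slots(1),
                       events=[ev])
    res = simulate_clade("((A,B),C);", params)
    ups = []
    for sp in ("A", "B"):
        cp = next(c for c in res.truth[sp] if c.slot == "dest0")
        gene = GeneModel("g", cp.chrom, cp.strand, sorted(cp.exons), "")
        ups.append(extract_upstream(res.genomes[sp], gene, 200).seq)
    block = conserved_block(ups, min_identity=0.7, min_length=100)
    assert block is not None
    lo, hi = block
    assert hi - lo >= 150
    assert lo <= -31 <= hi - 7          # covers the TATA box
    klf, foxa = scan_tf_sites(ups[0])
    assert any(lo <= o < hi for o, _ in klf)
    assert any(lo <= o < hi for o, _ in foxa)


# --------------------------------------------------------------------------
# carry-over classification

def _reports_for(carry: bool, seed=13):
    ev = PlannedEvent("A,B", "translocation_gain", "dest0",
                      source_slot="parent", introns_removed=8,
                      promoter_carryover=carry)
    params = SimParams(seed=seed, subst_rate=0.0, slots=default_slots(1),
                       events=[ev])
    res = simulate_clade("((A,B),C);", params)
    reports = {}
    for sp, slot in (("C", "parent"), ("A", "dest0")):
        cp = next(c for c in res.truth[sp] if c.slot == slot)
        gene = GeneModel("g", cp.chrom, cp.strand, sorted(cp.exons), "")
        reports[slot] = make_report(res.genomes[sp], gene, slot=slot)
    return reports


def test_carried_promoter_classified_true():
    r = _reports_for(True)
    verdict, ev = classify_carryover(r["parent"], r["dest0"])
    assert verdict
    assert ev["klf_offsets"] and ev["foxa3_offsets"]


def test_replaced_promoter_classified_false():
    r = _reports_for(False)
    verdict, ev = classify_carryover(r["parent"], r["dest0"])
    assert not verdict


def test_deleted_foxa3_site_flips_verdict():
    """Analog of a reporter construct lacking the foxa3 site: conserved block
    present but verdict false, evidence naming the missing site."""
    r = _reports_for(True)
    daughter = r["dest0"]
    (off, site) = daughter.foxa3_hits[0]
    i = len(daughter.upstream_seq) + off
    seq = daughter.upstream_seq
    daughter.upstream_seq = seq[:i] + "A" * 4 + "C" * 6 + seq[i + 10:]
    from retrotrace.promoter import scan_tf_sites as sts
    daughter.klf_hits, daughter.foxa3_hits = sts(daughter.upstream_seq)
    verdict, ev = classify_carryover(r["parent"], daughter)
    assert not verdict
    assert "foxa3" in ev["missing"]
    assert ev["conserved_block"] is not None


# --------------------------------------------------------------------------
# upstream tree

def test_identical_sequences_zero_distances():
    rng = np.random.default_rng(14)
    s = _with_site("TATAAAT", -31, seed=15)
    ut = upstream_tree({sp: s for sp in "ABC"}, {sp: -31 for sp in "ABC"})
    dists = ut.tree.tip_tip_distances()
    assert float(dists.data.max()) == pytest.approx(0.0, abs=1e-12)


def test_nj_recovers_generating_topology():
    rng = np.random.default_rng(16)
    base = _rand(rng, 160) + "TATAAAT" + _rand(rng, 24)  # TATA at -31
    def mutate(s, positions):
        out = list(s)
        for p in positions:
            out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
        return "".join(out)
    shared_ab = list(range(10, 40, 3))
    shared_cd = list(range(60, 120, 3))
    seqs = {"A": mutate(base, shared_ab + [5]),
            "B": mutate(base, shared_ab + [7]),
            "C": mutate(base, shared_cd + [122]),
            "D": mutate(base, shared_cd + [125])}
    ut = upstream_tree(seqs, {sp: -31 for sp in seqs})
    clades = [frozenset(t.name for t in n.tips()) for n in ut.tree.non_tips()]
    assert frozenset({"A", "B"}) in clades or frozenset({"C", "D"}) in clades


def test_species_without_tata_excluded():
    rng = np.random.default_rng(17)
    good = _with_site("TATAAAT", -31, seed=18)
    seqs = {sp: good for sp in "ABCD"}
    seqs["E"] = "AC" * 100
    ut = upstream_tree(seqs, {**{sp: -31 for sp in "ABCD"}, "E": None})
    assert ut.excluded == ["E"]
    assert sorted(t.name for t in ut.tree.tips()) == ["A", "B", "C", "D"]


def test_too_few_usable_sequences_rejected():
    s = _with_site("TATAAAT", -31, seed=19)
    with pytest.raises(RetrotraceError):
        upstream_tree({"A": s, "B": s}, {"A": -31, "B": -31})
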