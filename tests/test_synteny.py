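import random

import pytest

from retrotrace.core_io import AnnotatedGenome, GeneRecord, RetrotraceError, read_newick
from retrotrace.genemodel import GeneModel, VestigeState, cross_species_clone
from retrotrace.synteny import (SENTINEL, build_presence_matrix,
                                count_daughter_slots, extract_context,
                                match_slots)
from retrotrace.synthdata import SCENARIO_NEWICK, random_scenario, simulate_clade


def _gm(chrom="chr", strand="+", exons=((100, 200),)):
    return GeneModel("g", chrom, strand, [tuple(e) for e in exons], "A" * 100)


def _ctx_from(genome, interval, strand="+", occ=None, k=3):
    return extract_context(genome, "chr", interval, strand,
                           occ or _gm(exons=(interval,)), k=k)


def _toy_genome(symbols, length=2000):
    """Genes of 50 bp spaced 100 apart, in the given (symbol, strand) order."""
    genes = []
    for i, (sym, strand) in enumerate(symbols):
        s = 100 + i * 150
        genes.append(GeneRecord(f"g{i}", sym, "chr", strand, [(s, s + 50)]))
    return AnnotatedGenome("sp", {"chr": "A" * length}, genes)


# --------------------------------------------------------------------------
# extract_context

def test_fixture_basal_context_tail_to_tail(fixture_clade):
    g = fixture_clade.genomes["herring"]
    cp = next(c for c in fixture_clade.truth["herring"] if c.slot == "tgfb2l")
    lo = min(s for s, _ in cp.exons)
    hi = max(e for _, e in cp.exons)
    ctx = extract_context(g, cp.chrom, (lo, hi), cp.strand,
                          _gm(exons=cp.exons), exclude_symbols={"hce"})
    assert ctx.upstream[0] == ("tgfb2l", "+")
    assert ctx.downstream[0] == ("kcnk4", "-")


def test_fixture_zebrafish_host_insertion(fixture_clade):
    g = fixture_clade.genomes["zebrafish"]
    cp = next(c for c in fixture_clade.truth["zebrafish"] if c.slot == "aox5")
    lo = min(s for s, _ in cp.exons)
    hi = max(e for _, e in cp.exons)
    ctx = extract_context(g, cp.chrom, (lo, hi), cp.strand,
                          _gm(exons=cp.exons), exclude_symbols={"hce"})
    assert ctx.host_insertion == ("aox5", 14, "opposite")


def test_chromosome_end_padded_with_sentinels():
    genome = _toy_genome([("n1", "+")])
    ctx = _ctx_from(genome, (300, 400), k=3)
    assert ctx.upstream == [("n1", "+"), (SENTINEL, "."), (SENTINEL, ".")]
    assert all(s == SENTINEL for s, _ in ctx.downstream)


# --------------------------------------------------------------------------
# match_slots

def _ctx(species, symbols, strand="+"):
    genome = _toy_genome([(s, "+") for s in symbols[:2]]
                         + [(s, "+") for s in symbols[2:]])
    # focal locus between 2nd and 3rd gene
    genome.species_id = species
    iv = (100 + 1 * 150 + 60, 100 + 2 * 150 - 10)
    return _ctx_from(genome, iv, strand)


def test_identical_contexts_share_a_slot():
    a = _ctx("sp1", ["glo1", "slco3a1", "mctp2b", "zzz"])
    b = _ctx("sp2", ["glo1", "slco3a1", "mctp2b", "zzz"])
    out = match_slots([a, b])
    assert out[0] == out[1]


def test_three_species_one_conserved_slot():
    ctxs = [_ctx(sp, ["glo1", "slco3a1", "mctp2b", "x" + sp])
            for sp in ("salmon", "croaker", "medaka")]
    out = match_slots(ctxs)
    assert len(set(out.values())) == 1
    assert out[0] == "glo1"  # lexicographically smallest anchor


def test_two_of_three_anchors_merge_one_does_not():
    a = _ctx("sp1", ["a1", "a2", "a3", "a4"])
    b = _ctx("sp2", ["zz", "a2", "a3", "yy"])     # shares a2,a3 in order
    c = _ctx("sp3", ["qq", "a2", "rr", "ss"])     # shares only a2
    out = match_slots([a, b, c])
    assert out[0] == out[1]
    assert out[2] != out[0]


def test_order_reversal_not_merged():
    a = _ctx("sp1", ["a1", "a2", "a3", "a4"])
    b = _ctx("sp2", ["a4", "a3", "a2", "a1"])
    out = match_slots([a, b])
    assert out[0] != out[1]


def test_assignment_invariant_under_permutation():
    ctxs = [_ctx(f"s{i}", ["k1", "k2", "k3", f"u{i}"]) for i in range(5)]
    base = match_slots(ctxs)
    rng = random.Random(3)
    for _ in range(4):
        perm = list(range(5))
        rng.shuffle(perm)
        shuffled = [ctxs[i] for i in perm]
        out = match_slots(shuffled)
        assert [out[i] for i in range(5)] == [base[perm[i]] for i in range(5)]


# --------------------------------------------------------------------------
# presence matrix

def test_fixture_euteleost_parent_slot_row_pattern(fixture_report):
    table = fixture_report.matrix.table
    assert {table.loc[sp, "glo1"] for sp in
            ("salmon", "croaker", "tonguesole", "medaka")} == {"full"}
    assert {table.loc[sp, "glo1"] for sp in
            ("seabass", "stickleback", "tilapia")} == {"vestige"}
    assert table.loc["cichlid", "glo1"] == "absent"


def test_all_vestige_and_missing_species_cells():
    v = VestigeState("fragment", 0.5, 2)
    genome = _toy_genome([("b1", "+"), ("b2", "+"), ("b3", "+")])
    genome.species_id = "spA"
    ctx = _ctx_from(genome, (320, 390), occ=v)
    m = build_presence_matrix([ctx], {0: "slotX"}, species=["spA", "spB"])
    assert m.table.loc["spA", "slotX"] == "vestige"
    assert m.table.loc["spB", "slotX"] == "absent"


def test_conflicting_duplicate_cells_raise():
    genome = _toy_genome([("b1", "+"), ("b2", "+"), ("b3", "+")])
    genome.species_id = "spA"
    c1 = _ctx_from(genome, (320, 390), occ=VestigeState("fragment", 0.5, 2))
    c2 = _ctx_from(genome, (320, 390), occ=VestigeState("absent", 0.01, 0))
    with pytest.raises(RetrotraceError):
        build_presence_matrix([c1, c2], {0: "s", 1: "s"})


def test_matrix_invariant_under_input_order(fixture_clade):
    from retrotrace.pipeline import run_simulated
    rep = run_simulated(fixture_clade)
    t1 = rep.matrix.table
    rep2 = run_simulated(fixture_clade)
    assert t1.equals(rep2.matrix.table)


# --------------------------------------------------------------------------
# daughter slots

def test_fixture_euteleost_daughter_slots_is_four(fixture_report):
    eu = ["cichlid", "croaker", "medaka", "salmon", "seabass", "stickleback",
          "takifugu", "tetraodon", "tilapia", "tonguesole"]
    from retrotrace.synteny import PresenceMatrix
    sub = fixture_report.matrix.table.loc[eu]
    sub = sub[[c for c in sub.columns if (sub[c] != "absent").any()]]
    assert count_daughter_slots(PresenceMatrix(sub), "glo1") == 4


def test_parent_only_matrix_has_zero_daughters():
    genome = _toy_genome([("b1", "+"), ("b2", "+"), ("b3", "+")])
    genome.species_id = "spA"
    ctx = _ctx_from(genome, (320, 390))
    m = build_presence_matrix([ctx], {0: "b1"})
    assert count_daughter_slots(m, "b1") == 0
    with pytest.raises(RetrotraceError):
        count_daughter_slots(m, "nope")


def test_recovered_slots_equal_planted_destinations():
    """At substitution rate 0, slots recovered equal slots planted."""
    tree = read_newick(SCENARIO_NEWICK)
    for s in (7, 8, 9):
        params = random_scenario(2000 + s, subst_rate=0.0)
        res = simulate_clade(tree, params)
        seed_exons = list(res.ancestral.exons)
        contexts = []
        for sp in sorted(res.genomes):
            for (chrom, strand, lo, hi), occ in cross_species_clone(
                    seed_exons, res.genomes[sp]):
                if isinstance(occ, VestigeState) and occ.state == "absent":
                    continue
                iv = (occ.exons[0][0], occ.exons[-1][1]) \
                    if isinstance(occ, GeneModel) else \
                    (lo + occ.span[0], lo + occ.span[1])
                contexts.append(extract_context(res.genomes[sp], chrom, iv,
                                                strand, occ,
                                                exclude_symbols={"hce"}))
        n_slots = len(set(match_slots(contexts).values()))
        planted = 1 + len({e.payload["dest_slot"] for e in res.event_log
                           if e.kind == "translocation_gain"})
        assert n_slots == planted
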