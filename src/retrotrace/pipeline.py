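"""Orchestration: clone → synteny → events → promoter, plus truth scoring.

The pipeline consumes per-species annotated genomes, a rooted species tree
and the seed exon sequences of the focal family, and produces the full
inference: per-locus gene models or vestige grades, the species × slot
presence matrix, branch-placed intron-loss and translocation events,
co-timing verdicts, promoter carry-over calls and an upstream-region
distance tree.  When a ground-truth event log is supplied (simulated data)
it also scores recovery.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import events as ev_mod
from . import genemodel as gm_mod
from . import promoter as pr_mod
from . import synteny as sy_mod
from .core_io import AnnotatedGenome, RetrotraceError, SpeciesTree, read_fasta, read_gff3, read_newick
from .genemodel import GeneModel, VestigeState
from .synthdata import LogEntry, SimResult

logger = logging.getLogger(__name__)


@dataclass
class InferenceConfig:
    """Tunable thresholds of the inference stages (defaults per module)."""

    k_neighbors: int = 3
    min_anchors: int = 2
    min_intron: int = 40
    max_mismatch_frac: float = 0.15  # cross-species cloning tolerance
    window: int = 200
    min_identity: float = 0.7
    min_length: int = 100
    ancestral_intron_count: int | None = None  # default: len(seed_exons) - 1

    @classmethod
    def from_yaml(cls, path) -> "InferenceConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})


@dataclass
class RunReport:
    config: dict
    loci: pd.DataFrame                     # species, chrom, strand, interval, state, introns, coverage
    matrix: sy_mod.PresenceMatrix
    intron_events: list[ev_mod.EventPlacement]
    slot_gains: dict[str, ev_mod.EventPlacement]       # per slot (incl. ancestral at ROOT)
    slot_losses: dict[str, list[ev_mod.EventPlacement]]
    pseudo_events: list[ev_mod.EventPlacement]
    cotiming: ev_mod.CotimingVerdict
    carryover: dict[str, tuple[bool, dict]]            # per translocated slot
    upstream_newick: str | None
    parent_slot: str | None
    daughter_slot_count: int | None
    scorecard: pd.DataFrame | None = None

    def inferred_events(self) -> list[ev_mod.EventPlacement]:
        out = list(self.intron_events)
        out += [g for g in self.slot_gains.values() if g.branch_id != "ROOT"]
        for losses in self.slot_losses.values():
            out += losses
        out += self.pseudo_events
        return out


def _intron_tip_counts(loci_rows: list[dict]) -> dict[str, int]:
    tips: dict[str, int] = {}
    for row in loci_rows:
        if row["state"] == "full":
            n = row["introns"]
            tips[row["species"]] = min(tips.get(row["species"], n), n)
    return tips


def _nearest_ancestral_slot(slot: str, gains: dict[str, ev_mod.EventPlacement],
                            tree: SpeciesTree) -> str | None:
    """The slot whose gain branch most recently precedes this slot's gain."""
    b = gains[slot].branch_id
    best, best_size = None, None
    for other, g in gains.items():
        if other == slot:
            continue
        ob = g.branch_id
        if ob == "ROOT" or (b != "ROOT" and tree.is_strict_descendant(b, ob)):
            size = len(tree.leaves_under(ob)) if ob != "ROOT" else len(tree.leaves()) + 1
            if best is None or size < best_size:
                best, best_size = other, size
    return best


def run_inference(tree: SpeciesTree, genomes: dict[str, AnnotatedGenome],
                  seed_exons: list[str], config: InferenceConfig | None = None,
                  truth_log: list[LogEntry] | None = None) -> RunReport:
    """Execute the full comparative inference on annotated genomes."""
    cfg = config or InferenceConfig()
    if not genomes:
        raise RetrotraceError("no input genomes")
    missing = set(genomes) - set(tree.leaves())
    if missing:
        raise RetrotraceError(f"species not in tree: {sorted(missing)}")
    ancestral = cfg.ancestral_intron_count
    if ancestral is None:
        ancestral = len(seed_exons) - 1

    # -- stage 1: in-silico cloning of every family locus ------------------
    loci_rows: list[dict] = []
    contexts: list[sy_mod.SyntenyContext] = []
    reports_by_ctx: list[pr_mod.PromoterReport | None] = []
    for sp in sorted(genomes):
        genome = genomes[sp]
        for (chrom, strand, lo, hi), occ in gm_mod.cross_species_clone(
                seed_exons, genome, min_intron=cfg.min_intron,
                max_mismatch_frac=cfg.max_mismatch_frac):
            if isinstance(occ, GeneModel):
                interval = (occ.exons[0][0], occ.exons[-1][1])
                state, introns, cov = "full", occ.intron_count, 1.0
            else:
                if occ.state == "absent":
                    continue
                # tighten the padded search window to the aligned vestige span
                interval = (lo + occ.span[0], lo + occ.span[1]) if occ.span \
                    else (lo, hi)
                state, introns, cov = occ.state, -1, occ.coverage
            ctx = sy_mod.extract_context(genome, chrom, interval, strand, occ,
                                         k=cfg.k_neighbors,
                                         exclude_symbols={"hce"})
            contexts.append(ctx)
            reports_by_ctx.append(
                pr_mod.make_report(genome, occ, window=cfg.window)
                if isinstance(occ, GeneModel) else None)
            loci_rows.append(dict(species=sp, chrom=chrom, strand=strand,
                                  start=interval[0], end=interval[1],
                                  state=state, introns=introns, coverage=cov))
    loci = pd.DataFrame(loci_rows) if loci_rows else pd.DataFrame(
        columns=["species", "chrom", "strand", "start", "end",
                 "state", "introns", "coverage"])

    # -- stage 2: slots and presence matrix --------------------------------
    assignment = sy_mod.match_slots(contexts, min_anchors=cfg.min_anchors)
    matrix = sy_mod.build_presence_matrix(contexts, assignment,
                                          species=tree.leaves())
    for i, ctx in enumerate(contexts):
        loci_rows[i]["slot"] = assignment[i]
    if loci_rows:
        loci["slot"] = [r["slot"] for r in loci_rows]

    # -- stage 3: branch placement -----------------------------------------
    tips = _intron_tip_counts(loci_rows)
    intron_events = ev_mod.irreversible_loss_parsimony(tree, tips, ancestral)
    slot_gains: dict[str, ev_mod.EventPlacement] = {}
    slot_losses: dict[str, list[ev_mod.EventPlacement]] = {}
    pseudo: list[ev_mod.EventPlacement] = []
    for slot in matrix.slots:
        presence = matrix.table[slot].to_dict()
        gain, losses = ev_mod.dollo_presence_parsimony(tree, presence, slot=slot)
        slot_gains[slot] = gain
        slot_losses[slot] = losses
        pseudo += ev_mod.annotate_pseudogenization(tree, presence, slot=slot)
    translocations = [g for g in slot_gains.values() if g.branch_id != "ROOT"]
    cotiming = ev_mod.cotiming_report(tree, intron_events, translocations)

    # -- stage 4: parent/daughter bookkeeping ------------------------------
    parent_slot = None
    root_slots = [s for s, g in slot_gains.items() if g.branch_id == "ROOT"]
    if root_slots:
        parent_slot = sorted(root_slots)[0]
    # daughter slots: duplicative translocations, i.e. slots gained strictly
    # inside the gain clade of another (non-ancestral) slot
    daughter_count = 0
    for s, g in slot_gains.items():
        if g.branch_id == "ROOT":
            continue
        if any(o != s and og.branch_id != "ROOT"
               and tree.is_strict_descendant(g.branch_id, og.branch_id)
               for o, og in slot_gains.items()):
            daughter_count += 1

    # -- stage 5: promoter carry-over --------------------------------------
    slot_reports: dict[str, pr_mod.PromoterReport] = {}
    for i, ctx in enumerate(contexts):
        rep = reports_by_ctx[i]
        if rep is None:
            continue
        rep.slot = assignment[i]
        cur = slot_reports.get(rep.slot)
        if cur is None or rep.species_id < cur.species_id:
            slot_reports[rep.slot] = rep  # deterministic exemplar per slot
    carryover: dict[str, tuple[bool, dict]] = {}
    for slot, gain in slot_gains.items():
        if gain.branch_id == "ROOT" or slot not in slot_reports:
            continue
        ref_slot = _nearest_ancestral_slot(slot, slot_gains, tree)
        ref = slot_reports.get(ref_slot) if ref_slot else None
        if ref is None:  # fall back to any other slot's exemplar
            others = [r for s, r in sorted(slot_reports.items()) if s != slot]
            ref = others[0] if others else None
        if ref is None:
            continue
        carryover[slot] = pr_mod.classify_carryover(
            ref, slot_reports[slot], cfg.min_identity, cfg.min_length)

    # -- stage 6: upstream tree --------------------------------------------
    upstream_newick = None
    per_species: dict[str, pr_mod.PromoterReport] = {}
    for i, ctx in enumerate(contexts):
        rep = reports_by_ctx[i]
        if rep is not None and rep.species_id not in per_species:
            per_species[rep.species_id] = rep
    with_tata = {sp: r for sp, r in per_species.items() if r.tata_position is not None}
    if len(with_tata) >= 3:
        ut = pr_mod.upstream_tree({sp: r.upstream_seq for sp, r in with_tata.items()},
                                  {sp: r.tata_position for sp, r in with_tata.items()})
        upstream_newick = ut.newick

    report = RunReport(config=asdict(cfg), loci=loci, matrix=matrix,
                       intron_events=intron_events, slot_gains=slot_gains,
                       slot_losses=slot_losses, pseudo_events=pseudo,
                       cotiming=cotiming, carryover=carryover,
                       upstream_newick=upstream_newick,
                       parent_slot=parent_slot,
                       daughter_slot_count=daughter_count)
    if truth_log is not None:
        report.scorecard = score_against_truth(report, truth_log)
    return report


# --------------------------------------------------------------------------
# truth scoring

_KINDS = ("intron_loss", "translocation_gain", "copy_loss", "pseudogenization")


def score_against_truth(report: RunReport, event_log: list[LogEntry],
                        ) -> pd.DataFrame:
    """Per event kind: planted, recovered on the correct branch, spurious.

    Matching is exact on (kind, branch); slot identity is not compared
    because inferred slot ids are anchor-derived.
    """
    planted = [(e.kind, e.branch_id) for e in event_log]
    inferred = [(e.event_kind, e.branch_id) for e in report.inferred_events()]
    rows = []
    for kind in _KINDS:
        p = [b for k, b in planted if k == kind]
        f = [b for k, b in inferred if k == kind]
        remaining = list(f)
        recovered = 0
        for b in p:
            if b in remaining:
                remaining.remove(b)
                recovered += 1
        rows.append(dict(kind=kind, planted=len(p), recovered=recovered,
                         spurious=len(remaining)))
    return pd.DataFrame(rows).set_index("kind")


def recovery_rate(scorecard: pd.DataFrame) -> float:
    """Fraction of planted events recovered on their exact branch."""
    planted = int(scorecard["planted"].sum())
    if planted == 0:
        return 1.0
    return float(scorecard["recovered"].sum()) / planted


# --------------------------------------------------------------------------
# whole-run entry points

def run_simulated(result: SimResult, config: InferenceConfig | None = None,
                  ) -> RunReport:
    """Infer on a simulated clade and score against its ground truth."""
    seed_exons = list(result.ancestral.exons)
    return run_inference(result.tree, result.genomes, seed_exons,
                         config, truth_log=result.event_log)


def run_from_files(genome_dir, tree_path, seeds_fasta,
                   config: InferenceConfig | None = None) -> RunReport:
    """Load FASTA+GFF3 per species from a directory and run the inference.

    The directory must contain ``<species>.fa`` + ``<species>.gff3`` pairs.
    """
    species = sorted(f[:-3] for f in os.listdir(genome_dir) if f.endswith(".fa"))
    if not species:
        raise RetrotraceError(f"no input genomes in {genome_dir}")
    genomes = {}
    for sp in species:
        chroms = read_fasta(os.path.join(genome_dir, f"{sp}.fa"))
        gff = os.path.join(genome_dir, f"{sp}.gff3")
        genomes[sp] = read_gff3(gff, chroms, species_id=sp) if os.path.exists(gff) \
            else AnnotatedGenome(sp, chroms)
    tree = read_newick(tree_path)
    seeds = list(read_fasta(seeds_fasta).values())
    return run_inference(tree, genomes, seeds, config)


def write_report(report: RunReport, outdir) -> None:
    """Serialize the stage outputs (TSV/JSON/Newick) under ``outdir``."""
    import json
    os.makedirs(outdir, exist_ok=True)
    report.loci.to_csv(os.path.join(outdir, "loci.tsv"), sep="\t", index=False)
    report.matrix.table.to_csv(os.path.join(outdir, "presence_matrix.tsv"), sep="\t")
    with open(os.path.join(outdir, "events.tsv"), "w") as fh:
        fh.write("branch_id\tkind\tmagnitude\tslot\n")
        for e in sorted(report.inferred_events(),
                        key=lambda e: (e.event_kind, e.branch_id)):
            fh.write(f"{e.branch_id}\t{e.event_kind}\t{e.magnitude}\t{e.slot}\n")
    summary = {
        "parent_slot": report.parent_slot,
        "daughter_slot_count": report.daughter_slot_count,
        "cotimed_branches": report.cotiming.cotimed_branches,
        "lineage_verdicts": report.cotiming.lineage_verdicts,
        "carryover": {s: v for s, (v, _) in sorted(report.carryover.items())},
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    if report.upstream_newick:
        with open(os.path.join(outdir, "upstream_tree.nwk"), "w") as fh:
            fh.write(report.upstream_newick + "\n")
    if report.scorecard is not None:
        report.scorecard.to_csv(os.path.join(outdir, "scorecard.tsv"), sep="\t")
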