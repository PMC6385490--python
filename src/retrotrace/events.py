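"""Branch placement of intron-loss and translocation events by parsimony.

Intron counts are treated as an irreversible character: counts never
increase toward the tips (introns, once precisely excised by retrocopy, do
not come back).  Under that constraint the *latest* reconstruction — each
internal node takes the maximum of its children, capped by its parent — is
unique and minimizes total loss, and every branch where the value drops
carries a loss event of that magnitude.

Slot presence follows Dollo parsimony: a slot is gained once, on the branch
above the most recent common ancestor of all taxa carrying it (vestiges
count as presence), and may only be lost afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import RetrotraceError, SpeciesTree


@dataclass(frozen=True)
class EventPlacement:
    branch_id: str
    event_kind: str          # intron_loss | translocation_gain | copy_loss | pseudogenization
    magnitude: int = 0       # introns lost (intron_loss only)
    slot: str = ""           # slot id (translocation / loss / pseudogenization)


def irreversible_loss_parsimony(tree: SpeciesTree, tip_counts: dict[str, int],
                                ancestral_count: int, slot: str = "",
                                ) -> list[EventPlacement]:
    """Place intron-loss events on branches from tip intron counts.

    ``tip_counts`` maps species to the intron count of their (full-length)
    family copy; species absent from the map are unconstrained.  Internal
    nodes take the maximum of their children's values, capped by the parent
    (the root is fixed at ``ancestral_count``); a loss of magnitude
    (parent − child) is emitted on every branch where the value drops.
    Raises when a tip exceeds the ancestral count.
    """
    for sp, v in tip_counts.items():
        if v > ancestral_count:
            raise RetrotraceError(
                f"tip {sp} has {v} introns > ancestral {ancestral_count}")
        if v < 0:
            raise RetrotraceError(f"negative intron count at {sp}")

    value: dict[str, int | None] = {}
    for node in tree.postorder():
        if node.is_leaf:
            value[node.branch_id] = tip_counts.get(node.label)
        else:
            child_vals = [value[c.branch_id] for c in node.children
                          if value[c.branch_id] is not None]
            value[node.branch_id] = max(child_vals) if child_vals else None

    placements: list[EventPlacement] = []

    def descend(node, parent_count: int) -> None:
        v = value[node.branch_id]
        v = parent_count if v is None else min(v, parent_count)
        if v < parent_count:
            placements.append(EventPlacement(node.branch_id, "intron_loss",
                                             magnitude=parent_count - v, slot=slot))
        for c in node.children:
            descend(c, v)

    for child in tree.root.children:
        descend(child, ancestral_count)
    return placements


def dollo_presence_parsimony(tree: SpeciesTree, presence: dict[str, str],
                             slot: str = "") -> tuple[EventPlacement, list[EventPlacement]]:
    """Single-gain / multiple-loss placement for one slot-presence column.

    ``presence`` maps species to {"full", "vestige", "absent"}; full and
    vestige both count as presence for dating the gain.  The gain sits on
    the branch above the MRCA of all presence taxa; losses sit on the stems
    of the maximal all-absent subtrees inside the gain clade.  Raises on an
    all-absent column.
    """
    carriers = {sp for sp, st in presence.items() if st in ("full", "vestige")}
    if not carriers:
        raise RetrotraceError(f"slot {slot!r}: no taxon carries it")
    gain_node = tree.mrca(carriers)
    gain = EventPlacement(gain_node.branch_id, "translocation_gain", slot=slot)

    losses: list[EventPlacement] = []

    def all_absent(node) -> bool:
        return all(presence.get(lf, "absent") == "absent"
                   for lf in tree.leaves_under(node.branch_id))

    def collect(node) -> None:
        for c in node.children:
            if all_absent(c):
                losses.append(EventPlacement(c.branch_id, "copy_loss", slot=slot))
            else:
                collect(c)

    collect(gain_node)
    return gain, losses


def annotate_pseudogenization(tree: SpeciesTree, presence: dict[str, str],
                              slot: str = "") -> list[EventPlacement]:
    """Pseudogenization events on the stems of maximal all-vestige subtrees.

    A taxon whose copy at a slot is a vestige implies decay started no later
    than its terminal branch; contiguous all-vestige subtrees are annotated
    once, on their stem.
    """
    vest = {sp for sp, st in presence.items() if st == "vestige"}
    if not vest:
        return []
    out: list[EventPlacement] = []

    def all_vestige(node) -> bool:
        leaves = tree.leaves_under(node.branch_id)
        return leaves <= vest

    def collect(node) -> None:
        if node is not tree.root and all_vestige(node):
            out.append(EventPlacement(node.branch_id, "pseudogenization", slot=slot))
            return
        for c in node.children:
            collect(c)

    collect(tree.root)
    return out


@dataclass
class CotimingVerdict:
    cotimed_branches: list[str]
    lineage_verdicts: dict[str, str]   # leaf -> "co-timed" | "not co-timed" | "no events"


def cotiming_report(tree: SpeciesTree, intron_events: list[EventPlacement],
                    translocation_events: list[EventPlacement]) -> CotimingVerdict:
    """Branches carrying both an intron loss and a translocation gain, plus a
    per-lineage verdict.

    A lineage (root-to-leaf path) is "co-timed" iff every intron-loss branch
    on the path also carries a translocation gain and vice versa; lineages
    whose path carries neither kind are reported as "no events".
    """
    known = set(tree.branch_ids())
    for ev in intron_events + translocation_events:
        if ev.branch_id not in known:
            raise RetrotraceError(f"placement on foreign branch {ev.branch_id!r}")
    loss_branches = {e.branch_id for e in intron_events if e.event_kind == "intron_loss"}
    gain_branches = {e.branch_id for e in translocation_events
                     if e.event_kind == "translocation_gain"}
    both = sorted(loss_branches & gain_branches)
    verdicts: dict[str, str] = {}
    for leaf in tree.leaves():
        path = set(tree.path_to_root(leaf))
        l, g = path & loss_branches, path & gain_branches
        if not l and not g:
            verdicts[leaf] = "no events"
        elif l == g:
            verdicts[leaf] = "co-timed"
        else:
            verdicts[leaf] = "not co-timed"
    return CotimingVerdict(both, verdicts)
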