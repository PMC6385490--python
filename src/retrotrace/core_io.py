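"""Readers/writers and shared sequence utilities.

File formats handled here are deliberately narrow: plain multi-record FASTA,
a two-feature GFF3 dialect (``gene`` rows with ``ID=``/``symbol=`` and
``exon`` rows with ``Parent=``), and rooted Newick.  Coordinates are 0-based
half-open internally; GFF3 I/O converts to/from the format's 1-based closed
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class RetrotraceError(Exception):
    """Base class for package errors."""


class FormatError(RetrotraceError):
    """Malformed input file."""


# --------------------------------------------------------------------------
# sequence utilities

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide degeneracy sets.
IUPAC_NT: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Amino-acid alphabet with ``X`` as the any-residue wildcard.
IUPAC_AA: dict[str, frozenset[str]] = {a: frozenset(a) for a in _AA}
IUPAC_AA["X"] = frozenset(_AA)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS (standard code); trailing stop codon is stripped."""
    prot = str(Seq(cds).translate())
    return prot[:-1] if prot.endswith("*") else prot


def match_iupac(pattern: str, sequence: str, alphabet: str = "nt") -> list[int]:
    """All start positions where a degenerate pattern matches ``sequence``.

    ``alphabet`` is ``"nt"`` for IUPAC nucleotide codes or ``"aa"`` for amino
    acids with ``x`` as wildcard.  Matching is case-insensitive and
    sense-strand only.

    Raises :class:`ValueError` on a pattern symbol outside the alphabet.
    """
    table = IUPAC_NT if alphabet == "nt" else IUPAC_AA
    pat = pattern.upper()
    seq = sequence.upper()
    sets = []
    for sym in pat:
        try:
            sets.append(table[sym])
        except KeyError:
            raise ValueError(f"illegal {alphabet} code in pattern: {sym!r}")
    m = len(sets)
    if m == 0 or m > len(seq):
        return []
    hits = []
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in sets[j] for j in range(m)):
            hits.append(i)
    return hits


# --------------------------------------------------------------------------
# annotated genome

@dataclass
class GeneRecord:
    """One annotated gene: id, display symbol, location and exon intervals."""

    gene_id: str
    symbol: str
    chromosome: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # 0-based half-open, sorted by start

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def span(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class AnnotatedGenome:
    """Chromosome sequences plus ordered gene records for one species."""

    species_id: str
    chromosomes: dict[str, str]
    genes: list[GeneRecord] = field(default_factory=list)

    def validate(self) -> None:
        for chrom, seq in self.chromosomes.items():
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise FormatError(
                    f"{self.species_id}:{chrom}: non-ACGTN symbols {sorted(bad)}")
        for g in self.genes:
            if g.chromosome not in self.chromosomes:
                raise FormatError(f"gene {g.gene_id}: unknown chromosome {g.chromosome}")
            length = len(self.chromosomes[g.chromosome])
            prev_end = -1
            for s, e in g.exons:
                if not (0 <= s < e <= length):
                    raise FormatError(f"gene {g.gene_id}: exon [{s},{e}) out of bounds")
                if s < prev_end:
                    raise FormatError(f"gene {g.gene_id}: overlapping/unsorted exons")
                prev_end = e
            if g.strand not in "+-":
                raise FormatError(f"gene {g.gene_id}: bad strand {g.strand!r}")

    def genes_on(self, chrom: str) -> list[GeneRecord]:
        """Genes on a chromosome, sorted by start coordinate."""
        return sorted((g for g in self.genes if g.chromosome == chrom),
                      key=lambda g: g.start)

    def spliced_cds(self, gene: GeneRecord) -> str:
        """Concatenated exon sequence in the gene's sense."""
        seq = self.chromosomes[gene.chromosome]
        cds = "".join(seq[s:e] for s, e in gene.exons)
        return revcomp(cds) if gene.strand == "-" else cds


# --------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an insertion-ordered name → sequence map.

    Sequences are uppercased.  Duplicate record names and empty files raise
    :class:`FormatError`.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA record name: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise FormatError(f"empty or headerless FASTA: {path}")
    return out


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# --------------------------------------------------------------------------
# GFF3 (gene + exon features only)

def read_gff3(path, chromosomes: dict[str, str], species_id: str = "") -> AnnotatedGenome:
    """Parse a gene/exon GFF3 against already-loaded chromosome sequences.

    GFF3 coordinates (1-based closed) become internal 0-based half-open.
    """
    genes: dict[str, GeneRecord] = {}
    spans: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise FormatError(f"{path}:{lineno}: end < start")
            if chrom not in chromosomes:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom}")
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
            iv = (start_i - 1, end_i)  # to 0-based half-open
            if ftype == "gene":
                gid = a["ID"]
                genes[gid] = GeneRecord(gid, a.get("symbol", gid), chrom, strand, [])
                spans[gid] = iv
            elif ftype == "exon":
                parent = a["Parent"]
                if parent not in genes:
                    raise FormatError(f"{path}:{lineno}: exon before its gene {parent}")
                ps, pe = spans[parent]
                if iv[0] < ps or iv[1] > pe:
                    raise FormatError(f"{path}:{lineno}: exon outside gene span")
                genes[parent].exons.append(iv)
    for g in genes.values():
        g.exons.sort()
        if not g.exons:  # single-interval gene rows double as their own exon
            g.exons = [spans[g.gene_id]]
    genome = AnnotatedGenome(species_id, chromosomes, list(genes.values()))
    genome.validate()
    return genome


def write_gff3(genome: AnnotatedGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            s, e = g.span()
            fh.write(f"{g.chromosome}\tretrotrace\tgene\t{s + 1}\t{e}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};symbol={g.symbol}\n")
            for xs, xe in g.exons:
                fh.write(f"{g.chromosome}\tretrotrace\texon\t{xs + 1}\t{xe}\t.\t"
                         f"{g.strand}\t.\tParent={g.gene_id}\n")


# --------------------------------------------------------------------------
# species tree

@dataclass
class TreeNode:
    label: str | None
    children: list["TreeNode"]
    branch_id: str = ""  # id of the branch above this node
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """Rooted species tree with deterministic branch ids.

    The branch above a node is identified by the comma-joined, sorted set of
    leaf labels it subtends — stable under reserialization and child-order
    permutation.  The branch above the root is named ``ROOT``.
    """

    def __init__(self, root: TreeNode, multifurcating_root: bool = False):
        self.root = root
        self.multifurcating_root = multifurcating_root
        self._index: dict[str, TreeNode] = {}
        self._assign_ids(root)
        self.root.branch_id = "ROOT"
        self._index["ROOT"] = self.root

    def _assign_ids(self, node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            leaves = frozenset([node.label])
        else:
            leaves = frozenset()
            for ch in node.children:
                ch.parent = node
                leaves |= self._assign_ids(ch)
        node.branch_id = ",".join(sorted(leaves))
        self._index[node.branch_id] = node
        return leaves

    # -- queries ----------------------------------------------------------
    def leaves(self) -> list[str]:
        return sorted(n.label for n in self.postorder() if n.is_leaf)

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def rec(n: TreeNode) -> None:
            for c in n.children:
                rec(c)
            out.append(n)

        rec(self.root)
        return out

    def preorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def node(self, branch_id: str) -> TreeNode:
        try:
            return self._index[branch_id]
        except KeyError:
            raise RetrotraceError(f"no branch {branch_id!r} in tree")

    def branch_ids(self) -> list[str]:
        return sorted(self._index)

    def leaves_under(self, branch_id: str) -> set[str]:
        node = self.node(branch_id)
        if node is self.root:
            return set(self.leaves())
        return set(branch_id.split(","))

    def mrca(self, labels: set[str]) -> TreeNode:
        want = set(labels)
        # postorder visits children before parents, so the first superset
        # encountered is the most recent common ancestor
        for n in self.postorder():
            if want <= self.leaves_under(n.branch_id):
                return n
        raise RetrotraceError(f"labels {sorted(want)} not all in tree")

    def path_to_root(self, leaf: str) -> list[str]:
        """Branch ids from the leaf's terminal branch up to (excluding) ROOT."""
        node = self.node(leaf)
        path = []
        while node.parent is not None:
            path.append(node.branch_id)
            node = node.parent
        return path

    def is_strict_descendant(self, branch_id: str, ancestor_branch_id: str) -> bool:
        node = self.node(branch_id)
        anc = self.node(ancestor_branch_id)
        node = node.parent
        while node is not None:
            if node is anc:
                return True
            node = node.parent
        return False

    # -- serialization ----------------------------------------------------
    def to_newick(self) -> str:
        def rec(n: TreeNode) -> str:
            if n.is_leaf:
                return n.label
            return "(" + ",".join(rec(c) for c in n.children) + ")" + (n.label or "")

        return rec(self.root) + ";"


def read_newick(source) -> SpeciesTree:
    """Parse rooted Newick from a path or a literal string.

    Duplicate leaf labels raise :class:`FormatError`; a multifurcating root is
    accepted but flagged on the returned tree.
    """
    text = source if isinstance(source, str) and source.strip().endswith(";") \
        else open(source).read()
    try:
        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=True)
    except dendropy.utility.error.DataParseError as exc:
        raise FormatError(f"bad Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in dt.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate leaf labels in Newick tree")

    def conv(dn) -> TreeNode:
        if dn.is_leaf():
            return TreeNode(dn.taxon.label.replace(" ", "_"), [])
        return TreeNode(getattr(dn, "label", None),
                        [conv(c) for c in dn.child_nodes()])

    root = conv(dt.seed_node)
    return SpeciesTree(root, multifurcating_root=len(root.children) > 2)


def write_newick(tree: SpeciesTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
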