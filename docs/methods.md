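# Methods

## The inference problem

A gene family whose members were translocated by retrocopy leaves three
correlated footprints in a set of annotated genomes: (i) copies at new
genomic locations whose flanking-gene order is otherwise conserved across
species, (ii) precise loss of introns in those copies (spliced mRNA is the
template, so exonic sequence is untouched), and (iii) — in the unusual case
this package targets — conservation of the proximal promoter at the new
location. `retrotrace` reconstructs that history from per-species FASTA +
GFF3, a rooted Newick species tree and seed exon sequences of the family,
and tests whether translocations and intron losses map to the same branches
and whether the promoter traveled with the gene.

## Splice-aware CDS mapping

Exon–intron structures are determined by aligning a CDS to a genomic region
under the GT-AG rule: exons are gapless segments, gaps between them must
begin `GT`, end `AG` and be ≥ 40 nt (no minor GC-AG sites; the minimum
length is configurable). The dynamic program minimizes, lexicographically,

1. total mismatches,
2. intron count,
3. the sum of donor coordinates.

Minimizing mismatches first is safe for single-copy loci: re-aligning part
of the CDS elsewhere through an extra intron lands on unrelated sequence
(~75 % mismatched), so spurious introns are never bought; on substitution-
free data the objective reduces to "fewest introns over exact segments",
which the test suite checks against an exhaustive chain enumerator. The
donor-coordinate term makes genuinely tied chains resolve to the leftmost
donor, deterministically. A chain whose per-exon mismatch fraction exceeds
the tolerance (5 % by default; the pipeline uses 15 % to absorb cross-species
divergence) is rejected: if a within-tolerance chain exists once the GT-AG
constraint is dropped the locus is reported as a splice violation, otherwise
as unmappable.

Cross-species cloning searches every chromosome on both strands for each
seed exon (edlib infix alignment, ≤ 30 % edit distance), clusters hits into
candidate loci, and runs the mapper on each padded window; windows without a
valid gene model are graded as vestiges.

## Vestige grading

A locus occupant is compared with the reference CDS by local alignment
(match +1, mismatch −3, gap open −5, extend −2; both strands). *Coverage* is
the fraction of the reference spanned by the best alignment; *disruption*
counts frameshifting indels (net length ≢ 0 mod 3) plus premature stop
codons read in the reference frame. States: **full** ≥ 0.9 coverage with no
disruption; **fragment** 0.2–0.9; **short_fragment** 0.05–0.2; **absent**
< 0.05. The thresholds discretize a continuum of decay and are stated
explicitly so results are stable; the penalties keep random sequence below
the absent threshold at the sizes used here.

## Synteny slots

Each locus is described by up to k = 3 annotated flanking genes per side
(symbols and strands; chromosome ends padded with a sentinel that never
matches). Two loci share a slot when ≥ 2 anchors co-occur in a consistent
relative order; orientation differences are tolerated, order reversals are
not, and assignment is the transitive closure (union-find). Slot ids are the
lexicographically smallest anchor symbol (suffixed deterministically on the
rare collision between non-merging groups). A locus inside another gene's
intron is reported with the 1-based intron ordinal in the host's
transcription direction and the relative orientation, not with the host as
a neighbor. The focal gene's own orientation is recorded but never used for
slot identity, since translocated copies insert in either orientation.

## Branch placement

*Intron counts* are treated as irreversible: precisely excised introns do
not return. Tips carry the minimum intron count over their full-length
copies (species without one are unconstrained). Each internal node takes
the maximum of its children capped by its parent, the root being the
ancestral count; every drop emits a loss of that magnitude on that branch.
This reconstruction is the unique latest (closest-to-tips) one and attains
the exhaustive-enumeration minimum of total loss, which the suite verifies
on all random ≤ 6-leaf trees it draws. Two independent, equal-magnitude
losses on sister branches are inherently unidentifiable (parsimony prefers
one earlier shared loss); the scenario generator therefore never plants
sibling gains.

*Slot presence* follows Dollo parsimony: a single gain on the branch above
the MRCA of all carriers — vestiges count as presence, since a decayed copy
still dates the gain — and losses on the stems of the maximal all-absent
subtrees inside the gain clade. Maximal all-vestige subtrees are annotated
as pseudogenization events on their stems. Slots gained at the root are
ancestral locations; gains elsewhere are translocations, and gains nested
inside another non-root gain clade are counted as daughter (duplicative)
translocations.

*Co-timing*: the branch-level intersection of intron-loss and
translocation-gain placements. A root-to-leaf lineage is "co-timed" iff the
two branch sets agree along its path; same-branch resolution is the finest
the data support — whether the loss preceded the insertion within a branch
is not claimed.

## Promoter analysis

Offsets are negative coordinates relative to the TSS, modeled as the first
base of exon 1 (the simulated genes carry no 5′ UTR). Defaults: a 200 bp
upstream window; TATA consensus `TATAWAW`, 3′-most match starting in
−50…−20; klf3/17 `CWCCC` and foxa3 `TGTTTRCWYW`, sense strand only; the
subregion required for expression is parameterized as −192…−91. The
conserved block between upstream regions is computed positionally after
anchoring all windows at the TSS: the longest window whose identity is
≥ 0.7 for every sequence pair, reported as TSS-relative offsets, requiring
≥ 100 bp. Positional comparison is exact here because the simulator
introduces no indels outside pseudogenization; on real data an anchored
alignment would be needed first, which is the main caveat when applying the
carry-over classifier beyond the simulator. Carry-over is true iff the
daughter's block against the reference (nearest ancestral slot's exemplar)
contains a TATA box plus ≥ 1 klf and ≥ 1 foxa3 site inside −192…−91.

The upstream tree takes the 100 bp 5′ of each TATA box, computes
Jukes–Cantor-corrected p-distances (p capped at 0.74) and builds a
neighbor-joining tree (scikit-bio). NJ + JC is a deliberate, lightweight
substitute for maximum-likelihood tree building, which is outside this
package's scope; on substitution-free input the tree degenerates to a star.

## The synthetic-data generator

The generator is the package's stand-in for real assemblies and defines the
study conditions. One chromosome per synteny slot carries single-exon
anchor genes (~300–500 bp, 150–300 bp spacers) with an insertion point
between two named anchors, or a 16-exon host gene for intragenic
insertions. The ancestral focal gene has 9 exons (~60–140 bp) and 8 GT-AG
introns (60–120 bp); its 270-residue protein contains one
`HExxHxxGFxHExxRxDR` and one `SxMHY` active-site consensus and exactly six
cysteines; the 200 bp promoter carries `TATAAAT` at −31 and klf/foxa3 sites
inside −192…−91. Intron windows that could slide without changing the
spliced product are rejected at design time so planted boundaries are
unambiguous.

Retrocopy gains excise the 3′-most *n* introns (reverse transcription
initiates at the poly-A end, so partial processing is 3′-biased) and insert
promoter + gene at the destination midpoint, in the slot's configured
orientation; the promoter is the source copy's current 200 bp when carried,
otherwise random sequence. Pseudogenization keeps a contiguous 40–60 %
(fragment, 2 planted frameshifts) or 10–20 % (short, 1 frameshift) of the
spliced CDS; erasure replaces the whole span with random sequence — a
phenomenological stand-in for mutation saturation, not a mechanistic claim.

Substitutions are uniform single-nucleotide replacements at a per-branch,
per-site rate (default 0.002 for the worked-example clade; benchmarks use 0
and 0.01), with purifying selection on functional copies only: splice
dinucleotides, start/stop codons and the planted promoter motifs are held
fixed and nonsense substitutions are rejected, while vestiges drift freely.
This conditioning mirrors the observation that functional genes retain
canonical splice sites and expression over long evolutionary times, and it
is what the noisy-recovery benchmark (≥ 90 % required, 100 % observed at
0.01/site/branch) depends on. No indels, no rearrangements other than the
planted events, no realistic rate heterogeneity (GTR+Γ), and orthology is
by gene symbol, not sequence — passing tests therefore demonstrate the
inference logic, not robustness to annotation error or assembly
fragmentation.

The 16-leaf worked-example clade (three basal lineages, three otophysans,
ten euteleosts) plants the family's documented history; its defaults
(seed 42, rate 0.002) make every acceptance quantity reproducible
bit-for-bit. The random-scenario generator draws 1–2 gains on disjoint,
non-sibling internal branches of a fixed 8-leaf tree, each with 1–8 introns
removed and a fair coin for promoter carry-over, optionally followed by
decay of the source copy in one descendant (victims never share a cherry,
keeping each decay a distinct datable event).

## Numerical and design choices

- Coordinates are 0-based half-open internally; GFF3 I/O converts to/from
  1-based closed. Genome sequences are uppercased on read and restricted to
  ACGTN.
- Branch ids are the comma-joined sorted leaf sets of the subtended clade —
  stable under reserialization and child-order permutation (`ROOT` for the
  branch above the root).
- IUPAC matching is case-insensitive, sense-strand only; the protein
  alphabet uses `x` as the any-residue wildcard.
- All randomness flows from a single integer seed through one generator in
  fixed traversal order; identical parameters give byte-identical genomes,
  logs and reports.
- Truth scoring matches inferred to planted events on (kind, branch)
  exactly; slot identity is not compared because inferred slot ids are
  anchor-derived while planted ids are layout names.

## Known limitations

- Tandem near-identical copies at one locus are reported as one slot
  occupant; deduplication within a slot is out of scope.
- The carry-over classifier and conserved-block finder assume TSS-anchored,
  indel-free comparability of upstream windows (true in the simulator).
- Equal-magnitude intron losses on sister branches, and gains whose entire
  descendant clade loses the copy, are not identifiable from tip data;
  the benchmarks exclude them by construction rather than pretending to
  recover them.
- The species tree is an input; the package dates events on it but does not
  estimate it (the upstream NJ tree is descriptive, not the dating basis).
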