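# Methods

This note documents the models and procedures implemented in
`plastdrift`, the defaults and why they were chosen, the numerical
decisions, and what the synthetic validation does and does not show.

## Quadripartite detection

A plastome is modeled as a circular sequence carrying one pair of exact
inverted repeats (IRa = reverse complement of IRb). Detection is
seed-and-extend: every 24-mer of the circular sequence is looked up
against the reverse complement; each hit is extended to a maximal exact
match, using the invariant that `(i + j + L) mod n` is constant along an
inverted match to deduplicate seeds on the same anti-diagonal in O(1).
The longest match with non-overlapping arms wins; ties go to the smaller
single-copy ("SSC") length, then the smaller arm start, making output
deterministic. The longer gap between the arms is labeled LSC, the
shorter SSC, and the partition is reported in a canonical rotation with
LSC starting at 0 and junctions JLB/JSB/JSA/JLA defined as the
coordinate of the first base of the downstream region — so a gene ending
exactly at a junction is at distance 0.

Exact matching (no mismatch tolerance) is a deliberate default: assembled
plastomes have literally identical IR copies, and exactness is what makes
planted-boundary recovery a sharp test. `min_len` defaults to 1000 nt,
comfortably below the smallest IR the package is expected to meet
(~6.6 kb in the most IR-contracted genomes) and far above chance repeats.
If the only repeats at or above `min_len` have overlapping arms the
detector raises ("IR arms overlap"); with none at all it reports
`has_quadripartite=False` rather than guessing.

## Gene census

The classification rule operationalizes the field's qualitative
definition — a gene is a pseudogene when its best copy is truncated or
frame-shifted relative to a non-degraded reference — with explicit,
configurable thresholds (`CensusThresholds`):

| parameter | default | meaning |
|---|---|---|
| hit identity | 0.60 | minimum identity for a hit to count at all |
| hit coverage | 0.30 | minimum fraction of the reference CDS aligned |
| truncation coverage | 0.90 | below this, evidence = truncated |
| stop grace window | final 5% of codons | stops here are not "premature" |
| seed k-mer / step | 12 / 4 | search sensitivity |
| match / mismatch | +2 / −3 | census re-alignment scoring |

Search is an in-repo seeded aligner: k-mer hits on both strands are
clustered by diagonal, the best cluster defines a window (the genome is
indexed doubled so origin-wrapping genes stay contiguous), and the
reference CDS is re-aligned to the window with a Smith–Waterman/Gotoh
kernel. The census mismatch penalty is deliberately steeper (−3) than
the spacer-alignment default (−1): with +2/−1, a random extension into
flanking DNA has positive-score excursions often enough to drag a
truncated gene's coverage back over the 0.9 cutoff.

Evidence precedence is frameshift > premature stop > truncated: a 1-nt
indel also produces downstream in-frame stops, and the causal event is
the one reported. No hit above the acceptance thresholds means *lost*.
IR-duplicated genes collapse to one census entry with the best status
(present > pseudogene > lost): one intact copy means a functional gene.
The ratio denominator is always the number of valid CDSs in the supplied
reference record — reported in the output, never hard-coded.

Species are clustered on their `(ratio_lost, ratio_pseudo)` vectors with
average-linkage (UPGMA) on Euclidean distance via
`scipy.cluster.hierarchy`; the Newick output carries ultrametric branch
lengths (leaf depth = merge height / 2). Tests cross-check the heights
against an independent naive O(n³) agglomeration.

## Pairwise alignment

All pairwise DNA alignment is Needleman–Wunsch/Gotoh with affine gaps.
Defaults match +2 / mismatch −1 / gap open 10 / gap extend 2, emulating
ClustalW-style spacer-alignment settings; a gap run of length L costs
`open + (L−1)·extend` (the convention is documented because tools
disagree; all internal scores and the test oracles share it). Traceback
is deterministic: ties prefer diagonal, then the gap-in-second-sequence
move, then the other. The same kernel scores profile–profile columns, so
the progressive multiple aligner (pairwise identities → UPGMA guide tree
→ profile merges; BLOSUM62 for protein) is deterministic end to end.
Kernels are numba-compiled; the first call in a fresh environment pays a
few seconds of JIT cost.

## K2p spacer divergence

Spacers are enumerated between consecutive annotated features in each
genome's own rotation, including the origin-wrapping spacer; a spacer is
shared when the same unordered flanking-gene pair bounds a spacer in
every genome (gene symbols are compared case-insensitively with IR copy
suffixes stripped). Occurrences with reversed flank order are
reverse-complemented before alignment so inversions do not masquerade as
divergence. For each species pair, columns with a gap or ambiguous base
are excluded; P and Q are the transition and transversion proportions
over the remaining sites and `d = −½ ln[(1−2P−Q)√(1−2Q)]`. Saturation
((1−2P−Q) ≤ 0 or (1−2Q) ≤ 0) raises, and `rank_igs` skips such pairs
with a warning, dropping a region only if no pair is computable. Regions
are ranked by mean pairwise d (min and max also reported, since figures
in this literature sometimes print extremes); the ×100 "percent" columns
are presentation only.

## NG86 dN/dS

Synonymous site fractions come from the three possible changes at each
codon position, with changes to stop codons counted as nonsynonymous;
per-pair sites are averaged over the two sequences, which preserves
`S + N = 3 × codons` exactly. Observed differences in multi-hit codons
are averaged over all orderings of the differing positions, excluding
pathways through stop codons (falling back to all pathways when every
one is blocked). Proportions are Jukes–Cantor corrected,
`d = −¾ ln(1 − 4p/3)`. A proportion ≥ 0.75 leaves the correction
undefined; the lenient default reports NaN for that rate (a single-codon
synonymous difference legitimately has pS = 1), while strict mode — used
by the ω table — raises and the pair is skipped with a warning. ω is
undefined when dS = 0. The per-gene summary flags genes with median
pairwise ω > 1. This is a counting screen: it ranks and flags, but it is
not a maximum-likelihood branch-site test, and simulated regime tests
assert the flag, not any particular ω value.

## Barcode and primer design

A diagnostic site is strictly one-vs-rest: an alignment column where
exactly one species differs and the background is unanimous; a maximal
private gap run counts as one indel locus regardless of length; columns
containing ambiguous bases are skipped. Note a consequence the tests
pin down: a site private to species X separates X from *every* other
species, so private sites for all but one species already discriminate
every pair.

Primer windows are taken from maximal runs of fully conserved, gap-free
columns (the product-adjacent placement: a forward primer is the run's
3′ end, a reverse primer the next run's 5′ start, clamped to 18–27 nt),
filtered to GC fraction 0.30–0.70, and paired so every species' product
(primers included) lies within the requested 100–1000 nt bounds.
Candidates are scored by enclosed diagnostic sites and emitted greedily
without overlap; every emitted primer is re-scanned verbatim against
each species' ungapped sequence. Thermodynamics beyond the GC filter are
intentionally out of scope — markers of this kind are validated by PCR,
not by design-tool melting curves.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, at
a toy scale that keeps the full pipeline around a second per bundle:
~13.5 kb genomes (LSC 8500, IR 1400, SSC 2200) with 30 protein-coding
ORFs of 150–300 nt (uniform over sense codons, ATG…TAA, no codon-usage
bias), tRNA/rRNA placeholders with the rRNA block duplicated in the IRs,
and random spacers of ≥60 nt. `realistic_config()` scales to 120 kb / 80
genes; all recovery properties hold there too. Sentinel bases at the
region edges stop repeat extension exactly at the planted junctions, so
boundary recovery is a sharp equality test.

Per species, in order: gene deletions (feature and sequence excised);
pseudogenization by 1–2 nt frameshift indel, premature stop (codon
rewritten to TAA in the first 70% of codons), or terminal truncation
(≥13% of codons, codon-aligned); IR boundary migration at the IRb|SSC
junction (duplicating into or releasing from the IRs, keeping the mirror
exact; the moved window must be feature-free); optional SSC inversion;
and intergenic point mutations with per-site rate and transition
probability κ/(κ+2) (default κ=2, a typical plastid
transition/transversion ratio), restricted to single-copy spacers so the
IR mirror is preserved without mirrored edits. Frameshifts and stops are
planted with a 3-codon interior margin: an indel in the final couple of
codons does not meaningfully pseudogenize a gene, and a local aligner
rightly clips one or two terminal mismatching bases, so edge plants
would be untestable rather than wrong.

The default scenario's four species use deletion fractions 0.30–0.45 and
pseudogenization fractions 0.16–0.29 of the gene complement — the range
reported for heavily degraded holoparasite plastomes — plus IR shifts of
±15–45 nt and one SSC inversion. One long LSC spacer (+300 nt) is
reserved for marker planting and its flanking genes are protected from
random deletion (explicitly deleting a flank of a requested marker is an
error); the planted marker rewrites that spacer in every species with a
common template plus private edits (9 SNPs + 3 three-nt deletions by
default, round-robin across species, ≥8 nt apart so the alignment is
unambiguous). The "auto" hypervariable spacer is the longest single-copy
spacer excluding the marker-reserved one.

Determinism: one seed drives everything; each species uses an
independent substream keyed by CRC32 of its name, so adding a species
never changes the others. Same seed ⇒ byte-identical genomes, manifests
and pipeline outputs.

### What passing on synthetic data does and does not show

The generator plants *exact* IR copies, star-shaped species (no shared
tree structure), uniform substitution positions, and no sequencing or
annotation error. Recovery at 100% therefore validates the algorithms'
correctness on their stated assumptions — not robustness to IR copies
that differ by a few bases, annotation lift-over mistakes, codon-usage
bias, or alignment ambiguity in highly diverged spacers. The
accession-based checks (deposited GenBank records, fetched by
`scripts/fetch_accessions.py`) cover the real-data side: printed genome
sizes and GC contents, the extreme SSC/IR lengths, the shared-spacer
count, the most divergent spacer, the ω>1 flag, and the
pseudogene-ratio ordering.

## Problem sizes used by the acceptance script

`scripts/acceptance.py` uses 25 seeded bundles for IR-boundary recovery,
8 noise-free bundles (×4 species ×30 genes) for census recovery, 12
replicates of 10 kb sites for the K2p simulation check, 300 random codon
pairs (≤10 codons) for the NG86 oracle comparison, and 5 bundles each
for marker recovery and spacer ranking — sizes chosen so the whole
script completes in well under a minute while keeping Monte-Carlo checks
inside 3 standard errors.

## Known limitations

- IR detection is exact-match only; a `--max-mismatch` relaxation is an
  anticipated extension but not implemented.
- The census assumes one reference record defines the gene complement;
  genes absent from the reference are invisible.
- `extract_shared_igs` keeps the first occurrence of a duplicated flank
  pair, so an IR-internal spacer is represented once.
- The dN/dS screen is pairwise counting (NG86); it cannot attribute
  selection to branches or sites.
- Primer search reduces EcoPrimer-style machinery to conserved-window
  enumeration, which is correct and fast at the 4–6 species scale this
  package targets but not optimized for hundreds of taxa.
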