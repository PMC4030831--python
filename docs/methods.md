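# Methods

## Scope and data model

`itbkit` analyses the vertebrate β-integrin family at three levels: protein
sequences (cytosolic-domain alignment, identity, motifs, physicochemical
metrics), gene loci (span arithmetic over 1-based inclusive coordinates),
and the receptor-pairing network (which α subunits each β pairs with, and
what that implies about β-subunit evolution). Two curated fixtures are
packaged: a gene-summary table (coordinates, exon counts, subunit MW/length,
accessions, family labels) and a ligand→receptor pairing table. Family
labels are metadata, never inferred from sequence. Both fixtures preserve
their source verbatim, including internal inconsistencies: gene rows whose
printed kb size disagrees with their own coordinates are flagged
`self_consistent = False` rather than corrected, and the non-canonical
receptor name `αHβ7` is kept and reported by a validation pass instead of
being silently dropped.

## Sequence metrics

Gene span is `(end − start + 1)/1000` rounded to one decimal; rows printed
with descending coordinates (minus-strand convention) are normalised to
ascending order before the arithmetic. Molecular weight sums average
residue masses plus one water (18.0153 Da); the ambiguity code X has no
mass and is rejected. The isoelectric point solves `net_charge(pH) = 0` by
bisection on [0, 14] (default tolerance 0.01). The charge function uses the
Bjellqvist/Expasy pKa set, including the residue-specific N-terminal
adjustments and the C-terminal D/E adjustments, so it is directly
comparable to the common web-tool values; the full table is a module
constant (`itbkit.metrics`). The charge is strictly decreasing in pH, so
the bisection zero is unique.

## Alignment

Pairwise alignment is global Needleman–Wunsch with affine (Gotoh) gap
costs: a gap of length L costs `open + (L−1)·extend`, defaults BLOSUM62
with open 10 / extend 0.5. Tie-breaking is fixed (diagonal, then gap-in-b,
then gap-in-a) so results are bit-reproducible. The multiple aligner is
deliberately simple: sequences are folded into the running profile in input
order, scoring a residue against a column by the mean substitution score
over the column's non-gap residues. It is a configurable stand-in for
whichever interactive alignment editor a study might use, not a
reimplementation of any particular one — simulated alignments arrive
already aligned, so the heavy-duty MSA problem is out of the critical path.

Percent identity counts identical columns over mutually non-gap columns
(self-identity is therefore 100 regardless of gaps). Family summaries
report min/mean/max pairwise identity *and* the fraction of fully conserved
columns, because a single "identity" percentage is ambiguous between the
two. Consensus takes the columnwise plurality among non-gap residues, `X`
on ties, `-` for all-gap columns. Column filtering removes columns whose
gap fraction exceeds a threshold (default 0.0: any-gap columns drop,
emulating the exclusion of alignment-ambiguous regions before distance
analysis) and retains a provenance map of surviving column indices.

Motif scanning reports every N..Y 4-mer window, left to right, overlaps
allowed; a window with proline second is NPxY, any other is NxxY, and NPxY
windows are never double-reported as NxxY (NPxY ⊂ NxxY).

## Phylogenetics

Distances: for each pair, p = differing / mutually non-gap columns
(pairwise deletion), corrected with the Kimura protein transform
`d = −ln(1 − p − 0.2p²)`. The transform saturates at
`p_max = (−1+√1.8)/0.4 ≈ 0.854102`; a saturated pair is a hard error at the
point estimate and causes a bootstrap replicate to be dropped and counted
(`meta["dropped_replicates"]`) — failing loudly was preferred to imputing a
ceiling distance.

Neighbor joining follows Saitou–Nei: join the pair minimising
`Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`, with branch lengths from
the standard split formula, the final three lineages closed in star form.
Ties take the lowest (i, j) index pair; negative branch lengths are clamped
to zero with the deficit moved to the sister edge. On additive matrices NJ
is exact; the tests verify topology and all path lengths against the
generating tree for 4–8 taxa and cross-check topology against scikit-bio's
independent NJ.

Bootstrap: B column resamples with replacement (B = 100 by default),
replicate r seeded `seed + r`, full distance+NJ per replicate; each
non-trivial bipartition of the point-estimate tree is annotated with the
percentage of completed replicates containing it. Support is displayed on
the single point-estimate tree, not a consensus tree.

Rooting places the root at the midpoint of the outgroup's pendant edge
(for a two-leaf tree, the midpoint of the only edge); leaf-to-leaf path
lengths are preserved exactly. Newick parsing is delegated to dendropy;
writing is a small fixed-format serialiser (six-decimal lengths, supports
as internal labels) so that parse∘write is the identity and repeated runs
are byte-identical.

Family-group extraction is this package's operational definition of "the
groups the tree supports": collapse internal edges with support below the
threshold (default 90) into polytomies, remove the outgroup, then merge
top-level subtrees of the ingroup root whose family sets intersect; each
component is one group. Consequences worth knowing: a fully collapsed tree
yields one group per family; a single-family tree yields one group; a
non-monophyletic family (tracked per family in `resolved`) merges the
groups it straddles. The definition matches the natural reading of a
published tree in which the four groups hang off an effectively unresolved
deep radiation while the groups themselves are well supported.

## Pairing network

Ligand multiplicity counts table *rows* (a row naming several related
molecules is one ligand), the convention under which the published
per-subunit counts are reproduced. α-partner counts are distinct α tokens
co-occurring with the β across all receptors. The shared-α graph joins two
β nodes with weight |α(βi) ∩ α(βj)| when positive. Path inference is
breadth-first layering from a configurable root (default β4, the sole
hemidesmosomal subunit): each β attaches to its earliest-layer neighbour,
ties preferring larger shared-α weight then lexicographic order, reporting
the smallest shared α as the linking subunit. β nodes unreachable through
shared αs (β2 in the packaged table — its αL/αM/αX/αD set is private) are
attached beneath a placed member of a caller-supplied fallback group (for
example the phylogenetic partition, or the β2/β7 immune lineage) and marked
`via="unshared"`, or listed unplaced.

## Regulatory scanning

CpG islands use the classical thresholds (length ≥ 200, GC ≥ 0.5, obs/exp
CpG ≥ 0.6, all configurable) with `obs/exp = #CG · L / (#C · #G)`.
Detection seeds with 150-bp sliding windows (scan window deliberately
smaller than the minimum island, as in classical island scanners), merges
overlapping passing windows, snaps candidate boundaries to the outermost
CpG dinucleotides, walks a boundary inward CpG-by-CpG while its 100-bp
terminal window fails the thresholds, then trims until the whole region
passes and reports it if still ≥ 200 bp. Every reported island therefore
satisfies all thresholds as a whole region, which the tests re-verify by
brute force. N is a hard mask. BED output is 0-based half-open with islands
named `CpG<count>`.

miRNA sites: the seed is miRNA positions 2–8 (5′→3′; U≡T). A site anchors
on the 6mer core (reverse complement of positions 2–7); a position-8 match
at the 5′ flank and/or an adenine across from position 1 at the 3′ flank
upgrade it to 7mer-m8, 7mer-A1 or 8mer. Each occurrence is reported once
with its strongest type; bare 6mers are not reported. Site start is the
leftmost seed-complementary base (the A1 adenine is a property of the UTR,
not a complementary match, and is excluded from the span).

## Synthetic data: what it emulates, what it does not

Protein families evolve on a known guide tree under a 20-state equal-rates
model: per branch of length d, each site receives Poisson(d) substitution
events, each to a uniformly chosen different residue. The expected observed
difference between sequences at total distance d is
`E[p] = (19/20)(1 − e^{−20d/19})`, which the tests check by simulation
(0.38876 at d = 0.5; 0.18035 at d = 0.2). No indels are simulated: the
analysis path filters gapped columns before distances, so the tested path
is gapless by design.

The default guide tree mirrors the biological structure of interest: eight
families in four groups ({ITB1, ITB2, ITB7}, {ITB3, ITB5, ITB6}, {ITB4},
{ITB8}) radiating from a single unresolved ingroup root, with an outgroup
beyond. Family stems are 0.3 expected substitutions/site (any two families
≥ 0.6 apart), within-family tips 0.02–0.05, group-structure edges 0.15, and
the outgroup a further 0.4+0.1 from the ingroup root, 370 columns, two taxa
per family by default. These depths keep the deepest expected pairwise
p-distance near 0.71 — comfortably inside the Kimura domain even across
bootstrap fluctuation — while a 0.15 internal edge carries ~55 expected
substitutions, ample for near-unanimous support. Because the ingroup root
is a true four-way polytomy, the binary NJ tree must resolve it
arbitrarily; the support threshold is what collapses that arbitrary
resolution, and in a small fraction of seeds (measured ~1/20 at two taxa
per family) resampling noise pushes a spurious resolution past 90 — the
familiar star-tree artifact. Family monophyly at ≥90 support is robust
(no failures observed over 30 seeds at these conditions).

Motif-planted tails exclude asparagine and tyrosine from background
positions (and N/P/Y from motif wildcard slots), which makes accidental
N..Y windows impossible and the truth table exact — a deliberate
simplification; real tails contain both residues outside motifs. CpG
landscapes use a GC ≈ 30%, strongly CpG-depleted background with islands of
GC ≈ 65% and obs/exp ≈ 0.8; the returned truth interval is snapped to the
outermost CpG actually realised inside the planted region, since sampled
edge bases carrying no CpG are indistinguishable from background. Planted
600-bp islands are recovered at ≥90% reciprocal overlap in ~99% of seeds;
300-bp islands at obs/exp 0.8 are intrinsically fuzzier at the edges
(~91%). Random pairing tables draw each (ligand, β) incidence
independently and record exact truth counts.

Passing tests on these generators demonstrates correctness of the
algorithms under their stated models — clean substitution processes, sharp
composition boundaries, exact labels. They do not demonstrate robustness to
real-data phenomena: indels and alignment error, among-site rate variation
and empirical exchangeabilities, isoform heterogeneity, or browser-version
differences in regulatory track definitions.

## Pipeline and determinism

`run_full_analysis` executes load → (align) → filter → identities/motifs →
distances → NJ+bootstrap → root → family groups → pairing → report; any
stage failure aborts with the stage name. All outputs are plain text (TSV,
Newick, BED, DOT, JSON), every random draw derives from the single
configured seed, and the manifest records parameters plus a SHA-256 per
output file, so identical configuration reproduces byte-identical outputs.
Sequence-free configurations skip the phylogenetic stages and still produce
the pairing analysis.

`scripts/acceptance.py --seed N --out path.json` recomputes the headline
quantities at modest, fixed problem sizes (20 simulation seeds for recovery
rates, 25 additive matrices, 1 000 motif tails, 10 CpG landscapes, 500
miRNA/UTR pairs), chosen to complete in well under a minute on one CPU.

## Known limitations

- The progressive aligner is order-dependent and profile-naive; for
  publication-grade MSAs of real sequences, use a dedicated aligner and
  feed the aligned FASTA in with `aligned=True`.
- The Kimura protein correction ignores among-site rate variation and
  residue exchangeabilities; saturated pairs are refused rather than
  modelled.
- Group extraction is defined relative to the ingroup root after collapse;
  trees whose deep structure is genuinely resolved with high support will
  yield coarser partitions than a polytomy-based reading.
- CpG-island boundaries are window-resolution estimates sharpened by CpG
  snapping; agreement with any particular browser track implementation is
  not claimed.
- The star-tree artifact above means four-group recovery is a rate (~0.95),
  not a certainty, at the default two taxa per family; three taxa per
  family removed all observed failures.
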