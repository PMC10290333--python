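# Methods

## Codon alignments and reference numbering

All statistics operate on in-frame codon alignments. A reading frame
f ∈ {1,2,3} drops the f−1 leading alignment columns; a trailing remainder of
fewer than three columns is silently trimmed and logged. This convention
makes the common MHC exon geometries come out right: a 262-bp class I
exon 3 alignment at frame 2 yields 87 codon columns, a 258-bp class IIB
exon 2 alignment at frame 3 yields 85, and a 264-bp class I exon 2
alignment at frame 2 yields 87. Ambiguity codes are rejected at load rather
than resolved: the pathway-counting machinery downstream assumes definite
bases, and curated allele sets are unambiguous, so failing fast is safer
than guessing.

Amino-acid positions quoted in a reference numbering (HLA-A2 residues
92–179, HLA-DRB1 residues 9–93, and the like) are related to alignment
columns by globally aligning the ungapped reference fragment against the
alignment consensus with match = 1, mismatch = 0, gap = −1. Ties in the
traceback are resolved by the aligner's deterministic first path, so maps
are reproducible. Columns aligned to reference gaps are flagged unmapped
and simply drop out of mask-restricted analyses. The map is rejected when
fewer than half of the reference residues land on an identical consensus
residue — under this scoring nearly every residue gets *placed* regardless
of relatedness, so residue identity, not placement, is the meaningful
reliability signal.

## Diversity statistics

Segregating sites S and total mutations η treat a column as variable when
at least two distinct non-gap bases occur among sequences covering it;
columns observed in fewer than two sequences cannot segregate and are
skipped. k and π use pairwise deletion (a column counts for a pair only
when both members carry a base), matching the defaults of the classical
population-genetics tools, so on gap-free data π·L = k exactly. The
amino-acid p-distance pairwise-deletes gap and stop positions. Pairwise
identity follows a different dialect on purpose: every column where at
least one sequence has a base is scored, a gap against a base is a
mismatch, and gap–gap columns are excluded — the convention of the
alignment viewers that report "% identity". The two gap policies are kept
separate rather than unified because each reproduces the tool family it
emulates.

## dN/dS estimation

**NG86.** Per codon, each position contributes
(synonymous single-base alternatives)/(valid alternatives) to the
synonymous site count s, with alternatives creating stops excluded from
the denominator; n = 3 − s, so s + n = 3 identically. Differences between
two codons at one position are classified directly; at two or three
positions the synonymous/nonsynonymous split is averaged over the 2 or 6
orderings of intermediates. Orderings passing through a stop codon are
excluded from the average; in the degenerate case where every ordering
hits a stop, all orderings are used with stop steps counted nonsynonymous.
Proportions use pair-averaged site counts (p = d / mean sites across the
two sequences) and the Jukes–Cantor transform corrects for multiple hits.
A pair whose proportion reaches 3/4 has an undefined corrected distance
and is dropped from the mean with a count reported, rather than clipped —
clipping would bias means toward an arbitrary ceiling.

**PBL.** Each compared position is assigned to a degeneracy class
(nondegenerate, twofold, fourfold) from the strict rule "fourfold iff all
three alternatives synonymous, nondegenerate iff none" (stops count as
nonsynonymous alternatives), which resolves the isoleucine and
serine/arginine/leucine edge cases the classical Li-style classification
leaves implicit. A position whose class differs between the pair's two
codons contributes half a site to each class, and a substitution there is
split the same way. Kimura 2-parameter components per class are
A = ½ln(1/(1−2P−Q)) − ¼ln(1/(1−2Q)) and B = ½ln(1/(1−2Q)); then
dS = (L₂A₂ + L₄A₄)/(L₂+L₄) + B₄ and dN = A₀ + (L₀B₀ + L₂B₂)/(L₀+L₂).
Pairs where any required log argument is non-positive, or a required class
is empty (e.g. no fourfold sites inside a small mask), are dropped with a
count. PBL is therefore better suited to whole-exon analyses; NG86 is the
default for small site masks.

Both methods report means over all defined pairs; dN/dS is the ratio of
means and is reported as NA when mean dS = 0 (as happens for a
synonymous-invariant panel). Gamma-distributed rate variation is *not*
applied to these distances: rate-model parameters fitted for nucleotide
model selection are a different quantity, and the pairwise counting
methods as classically defined are uniform-rate.

## Bootstrap and Z-test

Variance of (dN − dS) comes from resampling codon columns with
replacement — one resampling per replicate shared by all sequences, the
standard codon-bootstrap semantics. Internally each replicate is a
multinomial weight vector over columns, so per-pair per-column counts are
precomputed once and every replicate is a matrix product; 1000 replicates
on a 30-sequence × 90-codon alignment take a fraction of a second.
Replicates in which every pair is undefined are dropped; more than half
dropped is an error. SE is the standard deviation (ddof = 1) across
replicates, Z = (dN − dS)/SE, and p = 1 − Φ(Z) one-sided. When SE = 0 with
dN = dS (e.g. a monomorphic alignment) the test reports Z = 0, p = 0.5;
SE = 0 with dN ≠ dS yields a degenerate p of 0 or 1 with a warning.

## Site-overlap permutation test

The observed 2×2 table [[overlap, a-only],[b-only, neither]] is scored by
Pearson χ² without continuity correction; the no-Yates choice was verified
against the full set of published PSS–PBR χ² values, all of which
reproduce from their printed counts only without the correction. The null
holds one mask fixed and redraws the other uniformly at fixed size.
Because the statistic depends on the redrawn mask only through its overlap
with the fixed one, the null distribution of the overlap is
hypergeometric; the sampling path draws overlaps from it directly, and
when C(n_sites, |mask_b|) ≤ 10⁵ the tail is computed exactly by
enumeration (flagged `exact`, no smoothing). Sampled p-values use the
(hits + 1)/(R + 1) estimator, which cannot return 0 and is stated in the
result metadata. Swapping the mask roles leaves the exact p unchanged by
the symmetry of the hypergeometric.

## Between-class comparison

Z = (d₁ − d₂)/√(SE₁² + SE₂²) on two (dN − dS, SE) estimates, each from a
codon bootstrap, with a one-sided p for the caller-declared direction.
Class II α1β1 comparisons can be run on concatenated alpha+beta codon
alignments built with `concat_alignments`; which alpha allele joins which
beta allele is a caller-supplied pairing table, since genotype-phase
information is external to the alignments themselves. Estimates produced
by different distance methods are compared with a warning rather than an
error — the formula is method-agnostic, but mixed-method comparisons
deserve a flag.

## Genotype QC

A *sample* is one (individual, replicate, amplicon) combination. The depth
filter removes samples whose total reads fall below the threshold
(default 100) and *flags* samples exceeding the allele cap (default 6,
i.e. three diploid loci) without removing them: genotypes above the cap
can reflect real copy-number variation and deserve scrutiny, not silent
deletion. Replicate reproducibility is 100·2|A∩B|/(|A|+|B|); under
independent per-allele dropout at rate d in each replicate its expectation
is ≈ 100·(1−d), which the simulator-based tests verify. Replicates are
collapsed to a consensus genotype by set union — the conservative
reconstruction when the upstream pipeline's collapsing rule is unknown;
this is a dialect choice and is documented as such. The expression
cross-check requires the full allele sequence to occur exactly as a
substring of a transcript on either strand: at 100% identity over
full-exon lengths this is equivalent to a stringent local-alignment
search, and it is reproducible bit-exactly.

## Synthetic data

The codon simulator evolves each allele independently from a random
sense-codon root (a star genealogy): truth bookkeeping stays exact per
branch, and the pairwise-divergence structure the statistics consume is
induced without the extra machinery of a coalescent — the cost is that
simulated panels lack the correlated ancestry of real allele genealogies,
so tests passing on them say nothing about phylogenetic non-independence.
Proposals are single-base changes with transitions weighted κ; proposals
creating stops are rejected; nonsynonymous proposals are accepted with
probability min(1, ω_site) and synonymous proposals with
min(1, 1/ω_site), so the realised nonsynonymous:synonymous rate ratio at
a site equals its ω on both sides of 1 (acceptance-thinning only the
nonsynonymous side cannot push the ratio above 1). Each branch stops after
a Poisson-distributed target of accepted synonymous substitutions
calibrated so the expected synonymous divergence between two alleles
equals `pairwise_ds` (default 0.10, in the range typical of
intra-population MHC panels); targets requiring saturated divergence are
rejected up front.

The genotype simulator draws two alleles per locus per individual from
per-locus pools (defaults: 130 individuals, 3 loci, ~30 alleles per pool,
a skewed frequency spectrum with one near-fixed allele at the first locus
emulating a nonclassical-locus signature), adds an extra locus copy with
a small CNV probability (default 0.03), gives a configurable fraction of
individuals a technical replicate (default 0.575) with independent 2%
per-allele dropout, draws negative-binomial read counts (mean ≈ 1900,
dispersion 1), and embeds a planted expressed subset (default 35% of the
pool) into transcripts with random flanks, half on the reverse strand.
`n_low_read` plants that many individuals below the depth threshold for
exercising the filter. What the simulator does *not* model: PCR chimeras
and clustering artifacts, recombination/gene conversion, and read-depth
dependence of allele recovery — so QC results on simulated data bound
only the arithmetic, not the upstream denoising.

## Calibration and problem sizes

`mhcsel.calibration.selection_test_rejection_rate` measures the rejection
rate of the one-tailed Z-test on the true mask over seeded simulation
replicates. The packaged calibration uses 30 alleles × 90 codons with a
20-codon mask, κ = 2, 1000 bootstrap replicates and 50 simulation
replicates per regime — large enough for a two-digit rate estimate while
keeping the whole calibration in seconds. Under ω = 6 on the mask the test
rejects at α = 0.05 in ≥ 80% of replicates (observed: all of them); under
neutrality the one-sided rejection rate stays at or below the nominal
level — NG86's uniform-rate site counting is slightly conservative under
transition bias, which is the safe direction for a positive-selection
test.

## Known limitations

* Recombination detection, site-wise Bayesian/ML selection inference
  (FUBAR/MEME), phylogenetics and haplotype reconstruction are out of
  scope; PSS sets are inputs here, not outputs.
* PBL distances are frequently undefined on very small masks (empty
  fourfold class) and on deeply diverged pairs (K2P saturation); such
  pairs are dropped and counted, so masked analyses should prefer NG86.
* The exact handling of alignment columns spanning indels (e.g. a 3-bp
  deletion segregating in a class IIB panel) follows pairwise deletion
  throughout; tools differ here, and small count-level discrepancies with
  other software are expected on indel-bearing panels.
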