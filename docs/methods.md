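# Methods

This note records the models, conventions and numerical choices behind
`herdgen`, and what the synthetic cohorts do and do not emulate.

## Genotype model and file conventions

Genotypes live in a samples × markers matrix of alternate-allele
dosages {0, 1, 2} with a single missing sentinel (−1). The coding is
file-stable: when reading PED, `allele_b` is the *second* allele
observed per marker scanning samples in file order, never the minor
allele — minor/major status depends on which samples are present and
would make the coding unstable under sample filtering. A consequence
of plain PED carrying no allele-order metadata is that an arbitrary
in-memory matrix round-trips through write→read only up to this
canonicalisation (a marker whose first-scanned carrier is
homozygous-alt gets its coding flipped); one write→read pass is
idempotent, and every statistic in the package is invariant to the
flip. Positions are 1-based; segment lengths are computed as
end − start, with endpoints reported inclusively.

Chromosome labels are strings from {1..29, X, Y, 0} (cattle
numbering); "0" is treated as unplaced. X/Y/0 are non-autosomal QC
classes — the package does not model sex-chromosome genetics.

## Quality control

Order of operations: (1) duplicate removal, (2) sample call-rate
filter, (3) marker statistics on the survivors, (4) marker filters.
Duplicates are unions of pairs with DST ≥ 0.99; each group keeps its
highest-call-rate member, ties broken by lexicographically smaller id
for deterministic reruns. Whether duplicates are removed before or
after marker statistics is a genuine ordering choice; computing marker
statistics on a deduplicated, well-called sample set avoids counting
the same genome twice in allele frequencies.

The report gives *marginal* per-rule counts — each rule evaluated
independently on the post-sample-QC marker set — plus the joint
survivor count. On real chips the rules overlap, so the marginals need
not sum to the total exclusions; on constructed fixtures with disjoint
classes they do, which is what the QC audit tests assert. The HWE rule
applies to autosomal non-indel markers only, using complete genotypes;
markers with zero calls are charged to the call-rate rule, not to
MAF/HWE (whose statistics are undefined there).

The exact HWE test uses the conditional distribution of the
heterozygote count given the allele counts and the "sum of outcomes no
more probable than observed" two-sided rule, without mid-p. Weights
N!/(n_a! h! n_b!)·2^h are computed as exact integers, so the returned
p-value is a rational number rounded once to float; the test suite
checks exact agreement with a Fraction-arithmetic full enumeration for
every genotype triple with N ≤ 50.

## Diversity and effective population size

All per-marker statistics derive from the allele frequency of the
marker's own non-missing genotypes. PIC uses the biallelic
specialisation of Botstein's expression; the effective allele number
is reciprocal expected homozygosity 1/(p²+q²), which lies in [1, 2]
for biallelic markers. PN (proportion polymorphic, MAF ≥ 0.01) is
computed on the post-sample-QC, *pre*-marker-QC marker set: after the
MAF filter every survivor is polymorphic by construction and PN would
be identically 1. The other cohort means are reported on the
QC-surviving markers. A per-individual observed-heterozygosity table
is also emitted, since cohort Ho is a mean across markers.

LD is the squared Pearson correlation of dosage vectors
(composite/genotype r², no phasing), computed pairwise-complete under
missingness. Ne estimation bins within-chromosome pairs by genetic
distance (bp × cM/Mb / 100 Morgans; 1 cM/Mb default, the standard
cattle-scale constant), subtracts 1/(2n) from the bin mean r² as the
finite-sample correction, and inverts Sved's E[r²] = 1/(1+4Nc) at the
bin midpoint. Defaults: 10 log-spaced bins over [0.005, 0.1] M. Ne is
reported per bin; no reconstruction of Ne trajectories over past
generations is attempted. Bins with non-positive corrected r² get NaN
rather than a negative size.

## Runs of homozygosity

The caller reproduces the scanning-window logic of the standard chip
tool with its default parameters (window 50 SNPs / ≤1 het / ≤5
missing, hit fraction 0.05, minimum 100 SNPs, 1 Mb, gap 1 Mb, density
50 kb/SNP), every parameter exposed. Candidate runs are maximal
stretches of markers whose covering-window homozygosity fraction
exceeds the threshold; they are trimmed to start and end on homozygous
non-missing calls, split at physical gaps, then filtered — in that
order, and the brute-force oracle in the tests applies the same rules
literally, marker by marker. Chromosomes with fewer markers than the
window are skipped with a log notice. X/Y/unplaced markers are
excluded before scanning, since the inbreeding coefficient is defined
on the autosomal genome. The F_ROH denominator defaults to the mapped
autosomal extent Σ(max − min position), with an explicit override for
a fixed genome-length constant.

## Kinship, PCA, trees, families

G follows VanRaden's first method (single shared denominator) with
in-sample allele frequencies by default; markers monomorphic at the
frequencies used are dropped from numerator and denominator. Missing
genotypes are mean-imputed (Z = 0) for G only; the IBS distance uses
pairwise-complete markers. With in-sample frequencies G is
column-centred (G·1 ≈ 0), which means every relationship estimate is
shrunk by roughly the average relatedness of the cohort: in a herd
where one family is a large fraction of the samples, true half-sib
pairs (expected 0.25) can fall toward or below the 0.1 family
threshold. The parameter-recovery tests therefore embed relative pairs
among a majority of unrelated animals, where the shrinkage is small;
on a deeply related cohort the family partition from the 0.1 rule is
conservative (it may split, never spuriously merge, related bulls).

PCA is the eigendecomposition of G itself (equivalent to PCA of
centred, scaled genotypes), coordinates eigenvector × √eigenvalue,
eigenvector signs fixed by making the largest-magnitude loading
positive.

Neighbor joining is the Saitou–Nei algorithm with the Q criterion.
Exact Q ties are structural when four nodes remain (complementary
pairs share Q), so ties are broken on the smallest id pair; negative
branch-length estimates are clamped to zero with the deficit moved to
the sibling branch, preserving the joined pair's distance. On additive
inputs the algorithm is exact (topology and branch lengths), which the
tests verify against simulated additive trees.

Family construction: bulls with pairwise G ≥ 0.1 are linked and
connected components become families — the weakest rule consistent
with "kinship ≥ 0.1 means same family", making no transitivity
assumption of its own. Cows join by argmax kinship over bulls (ties to
the smaller bull id), or fall to "other" when no bull reaches the
threshold; "other" cows are the ones a breeding plan may mate to any
bull.

## The synthetic cohort generator

Founders are simulated in linkage equilibrium with allele frequencies
drawn from a uniform MAF law (default U(0.05, 0.5)); descendants by
meiosis with Poisson crossovers (no interference) at 1 cM/Mb. Marker
spacing is uniform along each chromosome (29 autosomes of 85.9 Mb by
default, ≈2.49 Gb total). All LD and autozygosity in a pedigree cohort
therefore comes from the pedigree itself. QC decoy markers are
appended with genotypes *guaranteed* to realise their declared class:
"rare" decoys are monomorphic (in a cohort of ~46 diploids a realised
MAF below 0.01 implies zero minor copies, since 1/92 > 0.01);
HWE-violating decoys draw from a heterozygote-deficit law (het
probability × 0.1, the direction typical of genotyping artifacts and
inbreeding) and are rejection-sampled until the exact test rejects at
10⁻⁶ while MAF stays ≥ 0.01; low-call decoys raise the missingness
rate locally (40%); X/Y/unplaced decoys are autosomal-like noise with
a sex-chromosome label. Duplicate samples are exact genotype copies
with fresh ids; missingness is drawn i.i.d. per cell *after*
duplication, so duplicates differ only in their no-call patterns (and
either member may end up the better-called one).

The default study-shaped cohort emulates a 46-animal conservation
herd: 9 paternal half-sib bulls, 15 cows sired by them (three inbred
at F = 1/8 via sire × half-sister matings), 20 unrelated cows, and two
duplicate pairs, on a ~101 k marker layout whose decoy-class counts
(3157 rare, 66 HWE, 1010 low-call, 3785 X, 330 Y, 6267 unplaced, 174
indel) mirror a real chip's QC audit; the clean balance is 86,420
markers (2980 per autosome). Because the generator's violation classes
are disjoint while real chips' overlap, its joint survivor count sits
slightly above a real audit's.

What the simulation does *not* reproduce: background LD from ancient
population history (founders are in linkage equilibrium), so short
"background" ROH (1–5 Mb) are far rarer than in real cattle and total
ROH counts are correspondingly lower; realistic recombination maps and
marker ascertainment; sex-linked inheritance; genotyping error beyond
missingness. Passing tests therefore demonstrate correctness of the
algorithms and recovery of pedigree-scale structure, not calibration
to any particular breed's LD landscape. Drift-generated LD for
validating the Sved Ne estimator comes from a separate discrete
Wright–Fisher forward simulator (default: 100 diploids, 200
generations, 2000 markers on 20 chromosomes at 1 cM spacing, 50
sampled), under which the estimator recovers the census size to well
within ±50% at c̄ ≈ 0.01 M.

## Problem sizes and determinism

The test suite runs the heavy recoveries at reduced but sufficient
scale: 100 full-sib-mating offspring on a 5 × 100 Mb genome with 12.5 k
markers for F_ROH; 3 × 10 half-sib families with 5.2 k markers over 10
seeds for family recovery; 10 Wright–Fisher seeds for Ne. All
randomness in the package flows from explicit integer seeds; the
pipeline itself is deterministic, and its manifest (package version,
configuration echo, SHA-256 input checksums) suffices to re-run a
bundle bit-identically.

## Known limitations

* The Ne point estimates depend on binning and the assumed constant
  map rate; they are reference values, not calibrated estimates.
* The family rule inherits the in-sample-frequency shrinkage of G
  discussed above; with an external base-population frequency vector
  (supported by `grm_vanraden`) the shrinkage disappears.
* VCF import is read-only, biallelic, GT-only.
* No LD pruning before PCA, no bootstrap support on trees, no
  mate-allocation optimisation beyond the family/"other" rule.
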