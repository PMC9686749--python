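# herdgen

SNP-array conservation genetics for small livestock herds: genotype
quality control, genetic-diversity statistics, runs-of-homozygosity
inbreeding, genomic kinship, neighbor-joining clustering and
kinship-rule family construction — plus a pedigree cohort simulator
with known ground truth for validating every stage.

## The problem

Local livestock breeds on the edge of extinction are often kept as a
single small conservation herd with incomplete or wrong pedigree
records. Before a breeding plan can be written, the herd's real
genetic state has to be measured from marker data: how much diversity
is left, how inbred the animals are, which animals are close relatives,
and how the herd partitions into sire families so that within-family
matings can be avoided. `herdgen` implements that analysis for
biallelic SNP-chip genotypes of a cattle-like genome (autosomes 1–29,
with X/Y/unplaced markers handled as QC classes), end to end, from
PLINK-style PED/MAP text files to a report bundle of tables and trees.

Because conservation herds are small and their genotypes are usually
not public, the package ships a pedigree-structured cohort simulator
whose output carries a truth table (pedigree inbreeding coefficients,
family labels, injected duplicates, per-marker QC classes), so the
whole pipeline is testable against known answers.

## Methods at a glance

**QC.** Duplicate samples are flagged by identity-by-state similarity
DST = (N<sub>IBS2</sub> + ½N<sub>IBS1</sub>)/N<sub>valid</sub> ≥ 0.99,
keeping the better-called member of each group; samples with call rate
< 0.90 are dropped; markers are then filtered on MAF < 0.01, a
Hardy–Weinberg exact test at p < 10⁻⁶, call rate < 0.90, non-autosomal
location and indel status. The HWE test is the exact conditional test:
given the allele counts, P(n<sub>het</sub> = h) ∝ N!/(n<sub>a</sub>! h! n<sub>b</sub>!)·2<sup>h</sup>,
with the two-sided p-value summing outcomes no more probable than the
observed one (computed in exact integer arithmetic).

**Diversity.** Per marker with allele frequency p (q = 1 − p):
He = 2pq, Ho = observed heterozygote fraction, Botstein's
PIC = 1 − (p² + q²) − 2p²q², effective allele number Ae = 1/(p² + q²),
MAF = min(p, q). Effective population size comes from Sved's relation
E[r²] = 1/(1 + 4Nc): genotype-correlation r² of within-chromosome
marker pairs is binned by genetic distance c (constant cM/Mb map),
corrected by −1/(2n) for sample size, and inverted as
N<sub>e</sub> = (1/r²<sub>adj</sub> − 1)/(4c̄).

**ROH and F_ROH.** A PLINK-style scanning window (50 SNPs, ≤1
heterozygote, ≤5 missing, hit fraction 0.05) marks in-run markers;
maximal runs are trimmed to homozygous calls, split at gaps > 1 Mb and
filtered at ≥100 SNPs, ≥1 Mb and ≤50 kb/SNP density. F_ROH is the
summed ROH length over the autosomal genome length.

**Kinship and families.** The genomic relationship matrix follows
VanRaden's first method, G = ZZ′/(2Σp<sub>j</sub>(1−p<sub>j</sub>)) with
Z = M − 2p, so parent–offspring pairs sit near 0.5 and half sibs near
0.25. PCA is the eigendecomposition of G. Neighbor joining (Saitou–Nei)
on the IBS distance matrix yields the herd tree (Newick). Families:
bulls with pairwise G ≥ 0.1 share a family (connected components);
each cow joins her maximum-kinship bull's family if that kinship
reaches 0.1, otherwise she is "other" and may be mated to any bull.

## Worked example

Simulate a 22-animal herd (3 unrelated bulls, 4 daughters each, 6
unrelated cows, one duplicated sample, plus QC-decoy markers), then run
the pipeline:

```
herdgen simulate --config herd.json --out fixture/
herdgen run --ped fixture/cohort.ped --map fixture/cohort.map --out report/
```

which prints

```
22 samples, 8048 markers, 0 families -> fixture
21 samples, 7887 markers after QC; 3 families; report in report/
```

`report/qc_report.txt` shows the per-rule audit — the duplicate was
removed and the decoy markers caught (the MAF row exceeds the 12
injected monomorphic decoys because low-MAF founder markers can drift
to fixation in 21 animals, and the rules overlap as they do on real
chips):

```
Total number of SNPs                   8048
SNP with MAF < threshold               116
SNP not in Hardy-Weinberg equilibrium  4
SNP with callrate < threshold          16
SNPs on chromosome X                   10
SNPs on chromosome Y                   4
SNPs on chromosome 0                   8
insertion/deletion                     3
SNPs used after quality control        7887

Samples genotyped            22
Duplicate samples removed    1
Low-call-rate samples removed 0
Samples used after QC        21
```

`report/diversity.tsv` summarises cohort diversity on the surviving
markers (PN is computed before marker filtering, otherwise every
survivor would be polymorphic by construction):

```
Proportion of Polymorphic Markers (PN)  0.985586
Expected Heterozygosity (HE)            0.351907
Heterozygosity Observed (HO)            0.369495
Polymorphism Information Content (PIC)  0.280951
Effective Numbers of Alleles            1.60501
Minor Allele Frequency (MAF)            0.265255
```

and `report/families.tsv` assigns every animal: the three sires each
head a family containing their four daughters, and the six unrelated
cows land in "other" — exactly the simulated structure. The bundle
also contains ROH segments and per-animal F_ROH, the IBS and G
matrices, PCA coordinates, and Newick trees for all animals and for
the bulls alone.

The same pipeline is available as a library (`herdgen.run_pipeline`,
or the individual stage functions `apply_qc`, `marker_stats`,
`detect_roh`, `grm_vanraden`, `nj_tree`, `build_families`, …).

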