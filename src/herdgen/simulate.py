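"""Pedigree-structured synthetic SNP cohorts with known ground truth.

The study population this package targets — a small conservation herd
genotyped on a ~100 k SNP chip — has no public genotypes, so every
pipeline stage is exercised against simulated cohorts whose family
structure, inbreeding, duplicate samples and QC-violating markers are
known by construction.

Founders are drawn in linkage equilibrium with allele frequencies from
a configurable MAF law; descendants are produced by meiosis with
Poisson-distributed crossovers (no interference, 1 cM/Mb by default),
so linkage disequilibrium and autozygosity in the cohort arise purely
from the pedigree.  Drift-generated LD, which the Sved effective-size
estimator needs, comes from a separate discrete Wright–Fisher forward
loop (:func:`simulate_wright_fisher`).

QC decoy markers (rare, Hardy–Weinberg-violating, low-call-rate, X/Y/
unplaced, indel) are appended with genotypes guaranteed to realise
their declared class, so quality-control audits can assert exact
counts.  Note that in a cohort of ~46 diploids a realised MAF below
0.01 implies zero minor-allele copies (1/92 > 0.01), so "rare" decoys
are generated monomorphic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, Marker, SampleInfo, write_ped_map

__all__ = [
    "MatingRecord",
    "SimulationConfig",
    "TruthTable",
    "simulate_cohort",
    "write_fixture",
    "read_fixture_truth",
    "default_study_config",
    "pedigree_inbreeding",
    "simulate_wright_fisher",
]


@dataclass(frozen=True)
class MatingRecord:
    sire_id: str
    dam_id: str
    child_id: str
    child_sex: str  # "male" | "female"


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; ``seed`` is mandatory.

    ``founders`` lists (id, sex) pairs simulated in linkage
    equilibrium; ``pedigree`` lists matings in an order where parents
    precede children.  ``sampled_ids`` restricts the emitted cohort to
    a subset of individuals (parents may stay unsampled); None samples
    everyone.  Artifact-marker counts append QC decoys on top of the
    clean autosomal grid.
    """

    seed: int
    founders: list[tuple[str, str]]
    pedigree: list[MatingRecord] = field(default_factory=list)
    sampled_ids: list[str] | None = None
    family_truth: dict[str, str] = field(default_factory=dict)
    n_chromosomes: int = 29
    chromosome_length_bp: int = 85_900_000
    markers_per_chromosome: int = 2980
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    recomb_rate_cM_per_Mb: float = 1.0
    missing_rate: float = 0.0
    n_duplicate_pairs: int = 0
    n_x_markers: int = 0
    n_y_markers: int = 0
    n_unplaced_markers: int = 0
    n_indel_markers: int = 0
    n_rare_markers: int = 0
    n_hwe_violating_markers: int = 0
    n_low_call_markers: int = 0
    low_call_missing_rate: float = 0.4
    #: MAF law for decoy markers whose class is NOT frequency-based;
    #: bounded away from the rare/monomorphic regime so classes stay disjoint.
    decoy_maf_range: tuple[float, float] = (0.25, 0.45)

    def validate(self) -> None:
        counts = [self.n_chromosomes, self.markers_per_chromosome,
                  self.n_duplicate_pairs, self.n_x_markers, self.n_y_markers,
                  self.n_unplaced_markers, self.n_indel_markers,
                  self.n_rare_markers, self.n_hwe_violating_markers,
                  self.n_low_call_markers]
        if any(c < 0 for c in counts):
            raise ValueError("all marker/sample counts must be >= 0")
        n_artifacts = (self.n_x_markers + self.n_y_markers
                       + self.n_unplaced_markers + self.n_indel_markers
                       + self.n_rare_markers + self.n_hwe_violating_markers
                       + self.n_low_call_markers)
        if self.n_chromosomes * self.markers_per_chromosome == 0 and n_artifacts > 0:
            raise ValueError("artifact markers requested with a zero clean-marker budget")
        known = {fid for fid, _ in self.founders}
        children = set()
        for rec in self.pedigree:
            if rec.sire_id not in known or rec.dam_id not in known:
                raise ValueError(
                    f"pedigree references unknown parent for child {rec.child_id!r} "
                    "(parents must precede children)")
            if rec.child_id in known:
                raise ValueError(f"duplicate individual id {rec.child_id!r}")
            known.add(rec.child_id)
            children.add(rec.child_id)
        if self.sampled_ids is not None:
            missing_ids = set(self.sampled_ids) - known
            if missing_ids:
                raise ValueError(f"sampled_ids not in pedigree: {sorted(missing_ids)}")

    def all_ids(self) -> list[str]:
        return [fid for fid, _ in self.founders] + [r.child_id for r in self.pedigree]


@dataclass
class TruthTable:
    """Ground truth for scoring pipeline output against the simulation.

    ``samples``: one row per emitted sample (id, sex, f_ped, family,
    duplicate_of).  ``markers``: one row per marker (marker_id,
    qc_class) where qc_class partitions the marker set into
    {clean, rare, hwe, low_call, chrX, chrY, unplaced, indel}.
    ``duplicate_pairs``: (original_id, copy_id) tuples.
    """

    samples: pd.DataFrame
    markers: pd.DataFrame
    duplicate_pairs: list[tuple[str, str]]


# ---------------------------------------------------------------------------
# Pedigree inbreeding by path counting (tabular kinship recursion)
# ---------------------------------------------------------------------------

def pedigree_inbreeding(founders: list[str],
                        pedigree: list[MatingRecord]) -> dict[str, float]:
    """Inbreeding coefficient F per individual from the pedigree alone.

    F(child) = kinship(sire, dam), with founders unrelated and
    non-inbred; kinship by the standard recursive tabular method.
    """
    parents: dict[str, tuple[str, str] | None] = {f: None for f in founders}
    order: dict[str, int] = {f: 0 for f in founders}
    for i, rec in enumerate(pedigree, 1):
        parents[rec.child_id] = (rec.sire_id, rec.dam_id)
        order[rec.child_id] = i
    memo: dict[tuple[str, str], float] = {}

    def kin(a: str, b: str) -> float:
        key = (a, b) if order[a] >= order[b] else (b, a)
        if key in memo:
            return memo[key]
        x, y = key  # x is the younger (or equal)
        if x == y:
            p = parents[x]
            val = 0.5 * (1.0 + (kin(*p) if p else 0.0))
        else:
            p = parents[x]
            val = 0.5 * (kin(p[0], y) + kin(p[1], y)) if p else 0.0
        memo[key] = val
        return val

    out: dict[str, float] = {}
    for ind, p in parents.items():
        out[ind] = kin(*p) if p else 0.0
    return out


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def _gamete(hap_pair: np.ndarray, chrom_slices: list[slice],
            positions: np.ndarray, chrom_length: int,
            morgans_per_bp: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a (2, n_markers) haplotype pair."""
    out = np.empty(hap_pair.shape[1], dtype=np.int8)
    for sl in chrom_slices:
        length_morgan = chrom_length * morgans_per_bp
        n_xo = rng.poisson(length_morgan)
        phase = rng.integers(2)
        if n_xo == 0:
            out[sl] = hap_pair[phase, sl]
            continue
        xo_bp = np.sort(rng.uniform(0, chrom_length, size=n_xo))
        seg = np.searchsorted(xo_bp, positions[sl])
        choice = (phase + seg) % 2
        idx = np.arange(sl.start, sl.stop)
        out[sl] = hap_pair[choice, idx]
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _hwe_violating_column(p: float, n: int, het_factor: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Genotypes with a heterozygote deficit: P(het) = het_factor * 2pq,
    the remaining mass split between homozygotes in proportion p^2 : q^2."""
    q = 1.0 - p
    p_het = het_factor * 2 * p * q
    hom_scale = (1.0 - p_het) / (p * p + q * q)
    probs = [q * q * hom_scale, p_het, p * p * hom_scale]
    return rng.choice([0, 1, 2], size=n, p=probs).astype(np.int8)


def _hwe_column(p: float, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(2, p, size=n).astype(np.int8)


def simulate_cohort(cfg: SimulationConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Generate a genotyped cohort plus its :class:`TruthTable`.

    Deterministic given ``cfg.seed``.  Duplicate samples are exact
    genotype copies (fresh ids, suffix ``_dup``); missingness is drawn
    i.i.d. per cell *after* duplication, so duplicate pairs differ only
    in their no-call patterns.
    """
    cfg.validate()
    from .qc import hwe_exact_test  # local import to avoid a cycle at import time

    rng = np.random.default_rng(cfg.seed)

    # -- clean autosomal marker grid --------------------------------
    chrom_slices: list[slice] = []
    markers: list[Marker] = []
    positions_parts = []
    m_per = cfg.markers_per_chromosome
    spacing = cfg.chromosome_length_bp // (m_per + 1) if m_per else 0
    for c in range(1, cfg.n_chromosomes + 1):
        start = len(markers)
        pos = (np.arange(1, m_per + 1) * spacing).astype(np.int64)
        for k in range(m_per):
            markers.append(Marker(id=f"snp_{c}_{k + 1}", chromosome=str(c),
                                  position_bp=int(pos[k]),
                                  allele_a="A", allele_b="C"))
        positions_parts.append(pos)
        chrom_slices.append(slice(start, len(markers)))
    n_clean = len(markers)
    positions = (np.concatenate(positions_parts) if positions_parts
                 else np.empty(0, dtype=np.int64))

    lo, hi = cfg.founder_maf_range
    freqs = rng.uniform(lo, hi, size=n_clean)

    # -- founder haplotypes and pedigree descent --------------------
    morgans_per_bp = cfg.recomb_rate_cM_per_Mb / 100.0 / 1e6
    haplos: dict[str, np.ndarray] = {}
    sexes: dict[str, str] = {}
    for fid, sex in cfg.founders:
        haplos[fid] = (rng.random((2, n_clean)) < freqs).astype(np.int8)
        sexes[fid] = sex
    for rec in cfg.pedigree:
        gam_s = _gamete(haplos[rec.sire_id], chrom_slices, positions,
                        cfg.chromosome_length_bp, morgans_per_bp, rng)
        gam_d = _gamete(haplos[rec.dam_id], chrom_slices, positions,
                        cfg.chromosome_length_bp, morgans_per_bp, rng)
        haplos[rec.child_id] = np.stack([gam_s, gam_d])
        sexes[rec.child_id] = rec.child_sex

    sampled = cfg.sampled_ids if cfg.sampled_ids is not None else cfg.all_ids()
    dosage = np.stack([haplos[sid].sum(axis=0) for sid in sampled]) \
        if sampled else np.empty((0, n_clean), dtype=np.int8)
    dosage = dosage.astype(np.int8)
    n_core = len(sampled)

    marker_class = ["clean"] * n_clean

    # -- decoy / artifact markers -----------------------------------
    used_pos: set[tuple[str, int]] = {(m.chromosome, m.position_bp) for m in markers}

    def fresh_position(chrom: str) -> int:
        while True:
            p = int(rng.integers(1, cfg.chromosome_length_bp))
            if (chrom, p) not in used_pos:
                used_pos.add((chrom, p))
                return p

    extra_markers: list[Marker] = []
    extra_cols: list[np.ndarray] = []
    extra_class: list[str] = []
    dlo, dhi = cfg.decoy_maf_range
    maf_floor = max(1, int(np.ceil(0.01 * 2 * n_core))) if n_core else 0

    def decoy_genotypes() -> np.ndarray:
        # rejection-sample so the decoy does not stray into the rare/HWE classes
        for _ in range(200):
            col = _hwe_column(rng.uniform(dlo, dhi), n_core, rng)
            tot = int(col.sum())
            minor = min(tot, 2 * n_core - tot)
            if minor < maf_floor:
                continue
            counts = np.bincount(col, minlength=3)
            if hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2])) < 1e-6:
                continue
            return col
        raise RuntimeError("could not generate a clean decoy genotype column")

    autosome_cycle = [str(1 + (k % cfg.n_chromosomes))
                      for k in range(max(cfg.n_rare_markers, 0)
                                     + cfg.n_hwe_violating_markers
                                     + cfg.n_indel_markers
                                     + cfg.n_low_call_markers)]
    cyc = iter(autosome_cycle)

    for k in range(cfg.n_rare_markers):
        chrom = next(cyc)
        extra_markers.append(Marker(id=f"rare_{k + 1}", chromosome=chrom,
                                    position_bp=fresh_position(chrom),
                                    allele_a="A", allele_b=None))
        extra_cols.append(np.zeros(n_core, dtype=np.int8))  # monomorphic: MAF 0 < 0.01
        extra_class.append("rare")

    for k in range(cfg.n_hwe_violating_markers):
        chrom = next(cyc)
        for _ in range(200):
            col = _hwe_violating_column(rng.uniform(0.3, 0.45), n_core, 0.1, rng)
            tot = int(col.sum())
            minor = min(tot, 2 * n_core - tot)
            counts = np.bincount(col, minlength=3)
            if minor >= maf_floor and hwe_exact_test(
                    int(counts[0]), int(counts[1]), int(counts[2])) < 1e-6:
                break
        else:
            raise RuntimeError(
                "could not generate an HWE-violating genotype column; the "
                "cohort is probably too small for the exact test to reach "
                "the rejection threshold")
        extra_markers.append(Marker(id=f"hwe_{k + 1}", chromosome=chrom,
                                    position_bp=fresh_position(chrom),
                                    allele_a="A", allele_b="G"))
        extra_cols.append(col)
        extra_class.append("hwe")

    for k in range(cfg.n_indel_markers):
        chrom = next(cyc)
        extra_markers.append(Marker(id=f"indel_{k + 1}", chromosome=chrom,
                                    position_bp=fresh_position(chrom),
                                    allele_a="A", allele_b="AT"))
        extra_cols.append(decoy_genotypes())
        extra_class.append("indel")

    low_call_idx: list[int] = []
    for k in range(cfg.n_low_call_markers):
        chrom = next(cyc)
        extra_markers.append(Marker(id=f"lowcall_{k + 1}", chromosome=chrom,
                                    position_bp=fresh_position(chrom),
                                    allele_a="T", allele_b="C"))
        extra_cols.append(decoy_genotypes())
        extra_class.append("low_call")
        low_call_idx.append(n_clean + len(extra_cols) - 1)

    for label, count, cls in (("X", cfg.n_x_markers, "chrX"),
                              ("Y", cfg.n_y_markers, "chrY"),
                              ("0", cfg.n_unplaced_markers, "unplaced")):
        for k in range(count):
            extra_markers.append(Marker(id=f"{cls}_{k + 1}", chromosome=label,
                                        position_bp=fresh_position(label),
                                        allele_a="G", allele_b="T"))
            extra_cols.append(_hwe_column(rng.uniform(dlo, dhi), n_core, rng))
            extra_class.append(cls)

    if extra_cols:
        dosage = np.concatenate([dosage, np.stack(extra_cols, axis=1)], axis=1)
        markers = markers + extra_markers
        marker_class = marker_class + extra_class

    # -- duplicates (exact copies, fresh ids) -----------------------
    dup_pairs: list[tuple[str, str]] = []
    if cfg.n_duplicate_pairs:
        if cfg.n_duplicate_pairs > n_core:
            raise ValueError("more duplicate pairs than samples")
        originals = rng.choice(n_core, size=cfg.n_duplicate_pairs, replace=False)
        for oi in sorted(int(i) for i in originals):
            orig_id = sampled[oi]
            dup_id = orig_id + "_dup"
            dup_pairs.append((orig_id, dup_id))
            dosage = np.vstack([dosage, dosage[oi][None, :]])
            sampled = list(sampled) + [dup_id]
            sexes[dup_id] = sexes[orig_id]

    # -- missingness (i.i.d. per cell, after duplication) -----------
    n_total_samples = dosage.shape[0]
    n_total_markers = dosage.shape[1]
    rate = np.full(n_total_markers, cfg.missing_rate)
    for j in low_call_idx:
        rate[j] = cfg.low_call_missing_rate
    if rate.any():
        mask = rng.random((n_total_samples, n_total_markers)) < rate[None, :]
        dosage = dosage.copy()
        dosage[mask] = MISSING

    samples = [SampleInfo(id=sid, sex=sexes[sid]) for sid in sampled]
    g = GenotypeMatrix(samples=samples, markers=markers, dosage=dosage)

    # -- truth table -------------------------------------------------
    f_ped = pedigree_inbreeding([fid for fid, _ in cfg.founders], cfg.pedigree)
    dup_of = {d: o for o, d in dup_pairs}
    sample_truth = pd.DataFrame({
        "sample_id": sampled,
        "sex": [sexes[s] for s in sampled],
        "f_ped": [f_ped.get(dup_of.get(s, s), 0.0) for s in sampled],
        "family": [cfg.family_truth.get(dup_of.get(s, s), "other") for s in sampled],
        "duplicate_of": [dup_of.get(s, "") for s in sampled],
    })
    # marker_truth rows follow the sorted marker order of the matrix
    class_by_id = dict(zip([m.id for m in markers], marker_class))
    marker_truth = pd.DataFrame({
        "marker_id": g.marker_ids,
        "qc_class": [class_by_id[mid] for mid in g.marker_ids],
    })
    return g, TruthTable(samples=sample_truth, markers=marker_truth,
                         duplicate_pairs=dup_pairs)


# ---------------------------------------------------------------------------
# Fixture files
# ---------------------------------------------------------------------------

def write_fixture(g: GenotypeMatrix, t: TruthTable, outdir: os.PathLike | str) -> None:
    """Write PED/MAP plus the three truth TSVs into ``outdir``."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    write_ped_map(g, os.path.join(outdir, "cohort.ped"),
                  os.path.join(outdir, "cohort.map"))
    t.samples.to_csv(os.path.join(outdir, "sample_truth.tsv"), sep="\t", index=False)
    t.markers.to_csv(os.path.join(outdir, "marker_truth.tsv"), sep="\t", index=False)
    pd.DataFrame(t.duplicate_pairs, columns=["original_id", "duplicate_id"]) \
        .to_csv(os.path.join(outdir, "duplicate_pairs.tsv"), sep="\t", index=False)


def read_fixture_truth(outdir: os.PathLike | str) -> TruthTable:
    outdir = os.fspath(outdir)
    samples = pd.read_csv(os.path.join(outdir, "sample_truth.tsv"), sep="\t",
                          keep_default_na=False)
    markers = pd.read_csv(os.path.join(outdir, "marker_truth.tsv"), sep="\t")
    pairs = pd.read_csv(os.path.join(outdir, "duplicate_pairs.tsv"), sep="\t")
    return TruthTable(samples=samples, markers=markers,
                      duplicate_pairs=[tuple(r) for r in pairs.itertuples(index=False)])


# ---------------------------------------------------------------------------
# Study-shaped default cohort
# ---------------------------------------------------------------------------

def default_study_config(seed: int) -> SimulationConfig:
    """Configuration emulating the conservation-herd study cohort.

    46 genotyped animals (9 bulls, 37 cow samples) of which two pairs
    are duplicate submissions; the bulls are paternal half-sibs (one
    bull family), 15 cows are sired by those bulls (joining the bull
    family), three of them inbred via sire x paternal-half-sister
    matings, and 20 cows are unrelated founders ("other").  Marker
    class counts mirror the study chip's QC audit: 3157 rare, 66
    HWE-violating, 1010 low-call, 3785 X, 330 Y, 6267 unplaced, 174
    indel decoys on top of a clean 29-autosome grid (2980 markers per
    autosome, ~86 k clean SNPs, ~101 k total).
    """
    founders: list[tuple[str, str]] = [("S0", "male")]
    pedigree: list[MatingRecord] = []
    family: dict[str, str] = {}

    # 9 paternal half-sib bulls from founder sire S0
    for k in range(1, 10):
        founders.append((f"D{k}", "female"))
        pedigree.append(MatingRecord("S0", f"D{k}", f"B{k}", "male"))
        family[f"B{k}"] = "Family 1"

    # 3 inbred cows: bull x paternal-half-sister (F = 1/8)
    for k in range(1, 4):
        founders.append((f"D{9 + k}", "female"))
        pedigree.append(MatingRecord("S0", f"D{9 + k}", f"H{k}", "female"))
        pedigree.append(MatingRecord(f"B{k}", f"H{k}", f"C{k}", "female"))
        family[f"C{k}"] = "Family 1"

    # 12 further cows sired by the bulls from unrelated dams
    for k in range(4, 16):
        founders.append((f"D{9 + k}", "female"))
        sire = f"B{1 + (k - 4) % 9}"
        pedigree.append(MatingRecord(sire, f"D{9 + k}", f"C{k}", "female"))
        family[f"C{k}"] = "Family 1"

    # 20 unrelated founder cows
    for k in range(1, 21):
        founders.append((f"U{k}", "female"))
        family[f"U{k}"] = "other"

    sampled = ([f"B{k}" for k in range(1, 10)]
               + [f"C{k}" for k in range(1, 16)]
               + [f"U{k}" for k in range(1, 21)])

    return SimulationConfig(
        seed=seed,
        founders=founders,
        pedigree=pedigree,
        sampled_ids=sampled,
        family_truth=family,
        n_chromosomes=29,
        chromosome_length_bp=85_900_000,
        markers_per_chromosome=2980,
        founder_maf_range=(0.05, 0.5),
        missing_rate=0.02,
        n_duplicate_pairs=2,
        n_x_markers=3785,
        n_y_markers=330,
        n_unplaced_markers=6267,
        n_indel_markers=174,
        n_rare_markers=3157,
        n_hwe_violating_markers=66,
        n_low_call_markers=1010,
    )


# ---------------------------------------------------------------------------
# Wright–Fisher forward loop (drift-generated LD for Ne recovery)
# ---------------------------------------------------------------------------

def simulate_wright_fisher(seed: int,
                           n_diploids: int = 100,
                           n_generations: int = 200,
                           n_chromosomes: int = 20,
                           markers_per_chromosome: int = 100,
                           marker_spacing_bp: int = 1_000_000,
                           n_sample: int = 50,
                           founder_maf_range: tuple[float, float] = (0.1, 0.5),
                           recomb_rate_cM_per_Mb: float = 1.0) -> GenotypeMatrix:
    """Discrete-generation Wright–Fisher population, random mating.

    Each generation every offspring haplotype is a recombinant gamete
    from a uniformly chosen parent.  After ``n_generations`` of drift,
    ``n_sample`` diploids are genotyped; the LD they carry reflects the
    census size ``n_diploids``, which is what Sved's relation between
    r^2 and genetic distance should recover.
    """
    rng = np.random.default_rng(seed)
    m_per = markers_per_chromosome
    n_markers = n_chromosomes * m_per
    chrom_len = marker_spacing_bp * (m_per + 1)
    morgans_per_bp = recomb_rate_cM_per_Mb / 100.0 / 1e6

    positions_chr = (np.arange(1, m_per + 1) * marker_spacing_bp).astype(np.int64)
    chrom_slices = [slice(c * m_per, (c + 1) * m_per) for c in range(n_chromosomes)]
    positions = np.tile(positions_chr, n_chromosomes)

    lo, hi = founder_maf_range
    freqs = rng.uniform(lo, hi, size=n_markers)
    haps = (rng.random((2 * n_diploids, n_markers)) < freqs).astype(np.int8)

    for _ in range(n_generations):
        new = np.empty_like(haps)
        parents = rng.integers(n_diploids, size=2 * n_diploids)
        for gidx in range(2 * n_diploids):
            p = parents[gidx]
            pair = haps[2 * p:2 * p + 2]
            new[gidx] = _gamete(pair, chrom_slices, positions, chrom_len,
                                morgans_per_bp, rng)
        haps = new

    picks = rng.choice(n_diploids, size=n_sample, replace=False)
    dosage = (haps[2 * picks] + haps[2 * picks + 1]).astype(np.int8)
    samples = [SampleInfo(id=f"wf_{i + 1}") for i in range(n_sample)]
    markers = []
    for c in range(n_chromosomes):
        for k in range(m_per):
            markers.append(Marker(id=f"wf_{c + 1}_{k + 1}",
                                  chromosome=str(1 + c % 29),
                                  position_bp=int(positions_chr[k]),
                                  allele_a="A", allele_b="C"))
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage)
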