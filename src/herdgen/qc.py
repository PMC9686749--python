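"""Sample- and marker-level quality control for SNP-array cohorts.

Two stages, in the order real chip analyses run them:

1. sample QC — duplicate detection by identity-by-state similarity
   (DST >= 0.99 flags a technical duplicate; the member with the
   higher genotype call rate is kept) and a per-sample call-rate
   floor (>= 0.90);
2. marker QC on the surviving samples — minor allele frequency,
   Hardy–Weinberg exact test, marker call rate, chromosome class
   (autosomes 1..29 only) and indel exclusion.

The report carries MARGINAL per-rule exclusion counts (each rule
evaluated independently on the post-sample-QC marker set) plus the
joint survivor count; marginal counts may overlap, so they need not
sum to total exclusions on real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "DuplicateGroup",
    "pairwise_dst",
    "find_duplicates",
    "hwe_exact_test",
    "apply_qc",
]


@dataclass(frozen=True)
class QCThresholds:
    """Filtering thresholds; defaults follow the standard chip-QC recipe."""

    dst_duplicate: float = 0.99
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    marker_callrate_min: float = 0.90
    sample_callrate_min: float = 0.90
    drop_indels: bool = True

    def __post_init__(self) -> None:
        for name in ("dst_duplicate", "maf_min", "hwe_p_min",
                     "marker_callrate_min", "sample_callrate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class DuplicateGroup:
    """A set of mutually-duplicate samples and the single member retained."""

    members: tuple[str, ...]
    retained_id: str
    pairs: tuple[tuple[str, str], ...]  # all flagged (i, j) pairs, ids sorted


@dataclass
class QCReport:
    """Marker/sample exclusion audit in the shape of a chip-QC table."""

    n_markers_total: int = 0
    n_maf: int = 0
    n_hwe: int = 0
    n_marker_callrate: int = 0
    n_chr_x: int = 0
    n_chr_y: int = 0
    n_chr_unplaced: int = 0
    n_indel: int = 0
    n_markers_kept: int = 0
    n_samples_total: int = 0
    duplicate_groups: list[DuplicateGroup] = field(default_factory=list)
    samples_removed_duplicate: list[str] = field(default_factory=list)
    samples_removed_callrate: list[str] = field(default_factory=list)
    n_samples_kept: int = 0

    def to_text(self) -> str:
        rows = [
            ("Total number of SNPs", self.n_markers_total),
            ("SNP with MAF < threshold", self.n_maf),
            ("SNP not in Hardy-Weinberg equilibrium", self.n_hwe),
            ("SNP with callrate < threshold", self.n_marker_callrate),
            ("SNPs on chromosome X", self.n_chr_x),
            ("SNPs on chromosome Y", self.n_chr_y),
            ("SNPs on chromosome 0", self.n_chr_unplaced),
            ("insertion/deletion", self.n_indel),
            ("SNPs used after quality control", self.n_markers_kept),
        ]
        width = max(len(r[0]) for r in rows)
        lines = [f"{name:<{width}}  {count}" for name, count in rows]
        lines.append("")
        lines.append(f"Samples genotyped            {self.n_samples_total}")
        lines.append(f"Duplicate samples removed    {len(self.samples_removed_duplicate)}")
        lines.append(f"Low-call-rate samples removed {len(self.samples_removed_callrate)}")
        lines.append(f"Samples used after QC        {self.n_samples_kept}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Identity-by-state similarity
# ---------------------------------------------------------------------------

def pairwise_dst(g: GenotypeMatrix) -> tuple[list[str], np.ndarray]:
    """All-pairs DST similarity matrix.

    DST(i, j) = (N_IBS2 + 0.5 N_IBS1) / N_valid over markers called in
    both samples, which equals 1 - mean(|d_i - d_j|)/2.  Diagonal is 1;
    a pair with no mutually-called marker gets NaN.
    """
    n = g.n_samples
    if n < 2:
        raise ValueError("pairwise_dst needs at least 2 samples")
    d = g.dosage.astype(np.float64)
    valid = g.dosage != MISSING
    out = np.ones((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diff = np.abs(d[i] - d[i + 1:])
        nv = both.sum(axis=1).astype(np.float64)
        ssum = np.where(both, diff, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = 1.0 - ssum / (2.0 * nv)
        row[nv == 0] = np.nan
        out[i, i + 1:] = row
        out[i + 1:, i] = row
    return g.sample_ids, out


def find_duplicates(g: GenotypeMatrix,
                    thr: QCThresholds = QCThresholds()) -> list[DuplicateGroup]:
    """Flag duplicate samples at DST >= ``thr.dst_duplicate``.

    Transitive groups are resolved by keeping the single member with
    the highest call rate (ties go to the lexicographically smaller
    id); every other member is marked for removal.
    """
    ids, dst = pairwise_dst(g)
    call = dict(zip(ids, g.sample_call_rates()))
    n = len(ids)
    # union-find over flagged pairs
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(dst[i, j]) and dst[i, j] >= thr.dst_duplicate:
                pairs.append((i, j))
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i, j in pairs:
        groups.setdefault(find(i), [])
    for k in range(n):
        r = find(k)
        if r in groups:
            groups[r].append(k)

    out: list[DuplicateGroup] = []
    for members in groups.values():
        member_ids = sorted(ids[k] for k in members)
        best_rate = max(call[s] for s in member_ids)
        retained = min(s for s in member_ids if call[s] == best_rate)
        gp = tuple(sorted(tuple(sorted((ids[i], ids[j])))
                          for i, j in pairs if find(i) == find(members[0])))
        out.append(DuplicateGroup(members=tuple(member_ids),
                                  retained_id=retained, pairs=gp))
    out.sort(key=lambda grp: grp.members)
    return out


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Two-sided exact test of Hardy–Weinberg genotype proportions.

    Conditions on the observed allele counts: with N genotypes and the
    minor-allele count fixed, P(het = h) is proportional to
    N! / (n_a! h! n_b!) * 2^h over the feasible h of the correct
    parity.  The p-value sums P(h) over all h with P(h) <= P(observed).
    Exact integer arithmetic throughout, so the result is the rational
    p-value rounded once to float.  A monomorphic marker returns 1.
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het
    minor = min(n_a, n_b)
    if minor == 0:
        return 1.0
    # weights W(h) = N!/(hom_minor! h! hom_major!) * 2^h, exact integers
    weights: dict[int, int] = {}
    for h in range(minor % 2, minor + 1, 2):
        hom_minor = (minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            continue
        weights[h] = (math.comb(n, hom_minor) * math.comb(n - hom_minor, h)
                      * (1 << h))
    w_obs = weights[n_het]
    total = sum(weights.values())
    p_num = sum(w for w in weights.values() if w <= w_obs)
    return p_num / total


# ---------------------------------------------------------------------------
# Full QC pass
# ---------------------------------------------------------------------------

def _marker_maf(g: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per marker over non-missing genotypes;
    markers with no calls get NaN."""
    valid = g.dosage != MISSING
    n_valid = valid.sum(axis=0).astype(np.float64)
    alt = np.where(valid, g.dosage, 0).sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore"):
        p = alt / (2.0 * n_valid)
    p[n_valid == 0] = np.nan
    return np.minimum(p, 1.0 - p)


def _hwe_pvalues(g: GenotypeMatrix, mask: np.ndarray) -> np.ndarray:
    """Exact-test p-values for the masked markers (NaN elsewhere and for
    markers with no complete genotypes)."""
    out = np.full(g.n_markers, np.nan)
    dos = g.dosage
    cache: dict[tuple[int, int, int], float] = {}
    for j in np.nonzero(mask)[0]:
        col = dos[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        counts = np.bincount(col, minlength=3)
        key = (int(counts[0]), int(counts[1]), int(counts[2]))
        if key not in cache:
            cache[key] = hwe_exact_test(*key)
        out[j] = cache[key]
    return out


def apply_qc(g: GenotypeMatrix,
             thr: QCThresholds = QCThresholds()) -> tuple[GenotypeMatrix, QCReport]:
    """Run sample QC then marker QC; return the filtered matrix + report.

    Order: (1) remove duplicate samples (keep the best-called member of
    each group); (2) remove samples below the sample call-rate floor;
    (3) on the survivors compute per-marker MAF, HWE (autosomal
    non-indel markers only, complete genotypes only) and call rate;
    (4) drop markers failing any rule.  All marker counts in the report
    are marginal over the post-sample-QC set.
    """
    report = QCReport(n_markers_total=g.n_markers, n_samples_total=g.n_samples)

    # (1) duplicates
    removed: set[str] = set()
    if g.n_samples >= 2:
        groups = find_duplicates(g, thr)
        report.duplicate_groups = groups
        for grp in groups:
            removed.update(m for m in grp.members if m != grp.retained_id)
    report.samples_removed_duplicate = sorted(removed)
    keep_idx = [i for i, s in enumerate(g.samples) if s.id not in removed]
    g1 = g.subset(sample_idx=keep_idx)

    # (2) sample call rate
    rates = g1.sample_call_rates()
    low = [s.id for s, r in zip(g1.samples, rates) if r < thr.sample_callrate_min]
    report.samples_removed_callrate = low
    keep_idx = [i for i, s in enumerate(g1.samples) if s.id not in set(low)]
    g2 = g1.subset(sample_idx=keep_idx)
    report.n_samples_kept = g2.n_samples

    # (3) marker statistics on survivors
    chroms = np.array([m.chromosome for m in g2.markers])
    is_x = chroms == "X"
    is_y = chroms == "Y"
    is_un = chroms == "0"
    autosomal = ~(is_x | is_y | is_un)
    indel = np.array([m.is_indel for m in g2.markers], dtype=bool)
    maf = _marker_maf(g2)
    callrate = g2.marker_call_rates()
    hwe_p = _hwe_pvalues(g2, autosomal & ~indel)

    with np.errstate(invalid="ignore"):
        fail_maf = maf < thr.maf_min
        fail_hwe = hwe_p < thr.hwe_p_min
        fail_call = callrate < thr.marker_callrate_min
    # rules are only evaluable where the statistic is defined; a marker
    # with zero calls is caught by the call-rate rule, not MAF/HWE
    fail_maf = np.where(np.isnan(maf), False, fail_maf)
    fail_hwe = np.where(np.isnan(hwe_p), False, fail_hwe)

    report.n_maf = int(fail_maf.sum())
    report.n_hwe = int(fail_hwe.sum())
    report.n_marker_callrate = int(fail_call.sum())
    report.n_chr_x = int(is_x.sum())
    report.n_chr_y = int(is_y.sum())
    report.n_chr_unplaced = int(is_un.sum())
    report.n_indel = int(indel.sum())

    # (4) joint survivors
    fail_any = fail_maf | fail_hwe | fail_call | is_x | is_y | is_un
    if thr.drop_indels:
        fail_any = fail_any | indel
    keep_markers = np.nonzero(~fail_any)[0]
    report.n_markers_kept = int(keep_markers.size)
    g3 = g2.subset(marker_idx=keep_markers)
    return g3, report
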