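"""Genetic-diversity statistics and LD-based effective population size.

Per-marker quantities (all from the alternate-allele frequency p of
the same marker, q = 1 - p):

* MAF          min(p, q)
* He           2pq — expected heterozygosity under Hardy–Weinberg
* Ho           observed fraction of heterozygous genotypes
* PIC          1 - (p^2 + q^2) - 2 p^2 q^2 — Botstein's polymorphism
               information content, biallelic form (max 0.375 at p=0.5)
* Ae           1 / (p^2 + q^2) — effective number of alleles
               (reciprocal expected homozygosity, in [1, 2])

Effective population size is estimated by inverting Sved's relation
E[r^2] = 1 / (1 + 4 N c): within-chromosome marker pairs are binned by
genetic distance c (Morgans, from physical distance and a constant
cM/Mb map rate), the bin mean of the genotype-correlation r^2 is
corrected for finite sample size, and Ne = (1/r^2_adj - 1) / (4 c̄).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "MARKER_STAT_COLUMNS",
    "CohortDiversity",
    "NeEstimate",
    "marker_stats",
    "individual_heterozygosity",
    "cohort_diversity",
    "ld_r2",
    "default_ne_bins",
    "estimate_ne",
]

MARKER_STAT_COLUMNS = ("maf", "callrate", "ho", "he", "pic", "ae",
                       "polymorphic", "n_valid")

#: MAF bin edges used for the 0.1-wide frequency histograms.
_HIST_EDGES = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
_PIC_EDGES = np.array([0.0, 0.1, 0.2, 0.3, 0.375])


@dataclass
class NeEstimate:
    """Sved-inversion estimate in one genetic-distance bin."""

    c_low: float
    c_high: float
    c_mid: float
    n_pairs: int
    mean_r2: float
    mean_r2_adj: float
    ne: float  # NaN when mean_r2_adj <= 0 or >= 1


@dataclass
class CohortDiversity:
    """Cohort-level means and histograms over defined marker stats."""

    n_markers: int
    pn: float
    mean_maf: float
    mean_ho: float
    mean_he: float
    mean_pic: float
    mean_ae: float
    maf_histogram: pd.DataFrame
    pic_histogram: pd.DataFrame
    ne_estimates: list[NeEstimate] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Single-column summary table in the shape of a diversity report."""
        rows = {
            "Proportion of Polymorphic Markers (PN)": self.pn,
            "Expected Heterozygosity (HE)": self.mean_he,
            "Heterozygosity Observed (HO)": self.mean_ho,
            "Polymorphism Information Content (PIC)": self.mean_pic,
            "Effective Numbers of Alleles": self.mean_ae,
            "Minor Allele Frequency (MAF)": self.mean_maf,
        }
        return pd.DataFrame({"value": rows})


def marker_stats(g: GenotypeMatrix, maf_min: float = 0.01) -> pd.DataFrame:
    """Per-marker diversity statistics over non-missing genotypes.

    Returns a DataFrame indexed by marker id with columns
    ``MARKER_STAT_COLUMNS``; markers with zero calls carry NaN stats.
    ``polymorphic`` is MAF >= ``maf_min`` (the same floor the QC MAF
    rule uses, strict "<" for exclusion there, so >= here).
    """
    if g.n_samples < 1:
        raise ValueError("marker_stats needs at least one sample")
    valid = g.dosage != MISSING
    n_valid = valid.sum(axis=0).astype(np.float64)
    alt = np.where(valid, g.dosage, 0).sum(axis=0).astype(np.float64)
    het = np.where(valid, g.dosage == 1, False).sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n_valid)
        ho = het / n_valid
    p[n_valid == 0] = np.nan
    ho[n_valid == 0] = np.nan
    q = 1.0 - p
    he = 2.0 * p * q
    hom = p * p + q * q
    pic = 1.0 - hom - 2.0 * p * p * q * q
    ae = 1.0 / hom
    maf = np.minimum(p, q)
    callrate = n_valid / g.n_samples if g.n_samples else np.ones_like(n_valid)
    poly = maf >= maf_min
    return pd.DataFrame(
        {"maf": maf, "callrate": callrate, "ho": ho, "he": he, "pic": pic,
         "ae": ae, "polymorphic": poly, "n_valid": n_valid.astype(np.int64)},
        index=pd.Index(g.marker_ids, name="marker_id"))


def individual_heterozygosity(g: GenotypeMatrix) -> pd.DataFrame:
    """Observed heterozygosity per sample (fraction of called genotypes
    that are heterozygous) — the per-individual companion to Ho."""
    valid = g.dosage != MISSING
    n_valid = valid.sum(axis=1).astype(np.float64)
    het = (g.dosage == 1).sum(axis=1).astype(np.float64)
    with np.errstate(invalid="ignore"):
        ho = het / n_valid
    return pd.DataFrame({"sample_id": g.sample_ids, "n_called": n_valid.astype(int),
                         "ho": ho}).set_index("sample_id")


def _histogram(values: np.ndarray, edges: np.ndarray, label: str) -> pd.DataFrame:
    counts, _ = np.histogram(values, bins=edges)
    # np.histogram's last bin is closed on the right, matching [0.4, 0.5]
    return pd.DataFrame({
        "bin_low": edges[:-1], "bin_high": edges[1:], "count": counts,
        "proportion": counts / counts.sum() if counts.sum() else counts * 0.0,
    }).rename_axis(label)


def cohort_diversity(stats: pd.DataFrame,
                     ne_estimates: list[NeEstimate] | None = None) -> CohortDiversity:
    """Aggregate :func:`marker_stats` output into cohort-level summaries.

    Means run over markers with defined stats; PN is the fraction of
    defined markers that are polymorphic; the MAF/PIC histograms cover
    polymorphic markers only.
    """
    defined = stats.dropna(subset=["maf"])
    if defined.empty:
        raise ValueError("no marker has defined statistics")
    poly = defined[defined["polymorphic"]]
    return CohortDiversity(
        n_markers=len(defined),
        pn=len(poly) / len(defined),
        mean_maf=float(defined["maf"].mean()),
        mean_ho=float(defined["ho"].mean()),
        mean_he=float(defined["he"].mean()),
        mean_pic=float(defined["pic"].mean()),
        mean_ae=float(defined["ae"].mean()),
        maf_histogram=_histogram(poly["maf"].to_numpy(), _HIST_EDGES, "maf"),
        pic_histogram=_histogram(poly["pic"].to_numpy(), _PIC_EDGES, "pic"),
        ne_estimates=ne_estimates or [],
    )


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(g: GenotypeMatrix, pair: tuple[int, int]) -> float:
    """Composite (genotype-correlation) r^2 for one marker pair.

    Squared Pearson correlation of the dosage vectors over samples
    called at both markers; NaN if either marker has zero variance on
    the shared samples or fewer than 2 shared calls.
    """
    j1, j2 = pair
    x = g.dosage[:, j1].astype(np.float64)
    y = g.dosage[:, j2].astype(np.float64)
    ok = (g.dosage[:, j1] != MISSING) & (g.dosage[:, j2] != MISSING)
    x, y = x[ok], y[ok]
    if x.size < 2:
        return float("nan")
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(min(1.0, cov * cov / (vx * vy)))


def _pairwise_r2_block(dos: np.ndarray) -> np.ndarray:
    """Pairwise-complete genotype r^2 for all marker pairs of a block.

    ``dos``: (n_markers, n_samples) with MISSING sentinels.  Returns an
    (m, m) matrix with NaN where undefined.
    """
    m_mask = (dos != MISSING).astype(np.float64)
    x = np.where(dos != MISSING, dos, 0).astype(np.float64)
    x2 = x * x
    n = m_mask @ m_mask.T
    sx = x @ m_mask.T          # sum of marker-i dosages over shared samples
    sxx = x2 @ m_mask.T
    sxy = x @ x.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx * sx
        r2 = (cov * cov) / (varx * varx.T)
    r2[(n < 2) | (varx <= 0) | (varx.T <= 0)] = np.nan
    return np.minimum(r2, 1.0)


def default_ne_bins(n_bins: int = 10,
                    c_min: float = 0.005,
                    c_max: float = 0.1) -> list[tuple[float, float]]:
    """Log-spaced genetic-distance bins (Morgans) for Ne estimation."""
    edges = np.geomspace(c_min, c_max, n_bins + 1)
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def estimate_ne(g: GenotypeMatrix,
                bins: list[tuple[float, float]] | None = None,
                map_rate_cM_per_Mb: float = 1.0,
                maf_min: float = 0.01) -> list[NeEstimate]:
    """Sved-relation Ne per genetic-distance bin.

    Uses autosomal polymorphic markers; genetic distance between two
    markers on the same chromosome is bp distance x map rate / 1e8
    Morgans.  Per bin the mean r^2 is reduced by 1/(2n) (n = samples,
    unphased-genotype finite-sample correction) before inversion
    Ne = (1/r^2_adj - 1)/(4 c̄) at the bin midpoint c̄.
    """
    if bins is None:
        bins = default_ne_bins()
    bins = sorted(bins)
    stats = marker_stats(g, maf_min=maf_min)
    auto = g.autosomal_mask()
    usable = auto & stats["polymorphic"].to_numpy()
    edges = np.array([b[0] for b in bins] + [bins[-1][1]])

    sums = np.zeros(len(bins))
    counts = np.zeros(len(bins), dtype=np.int64)
    chroms = np.array([m.chromosome for m in g.markers])
    positions = np.array([m.position_bp for m in g.markers], dtype=np.float64)
    for chrom in pd.unique(chroms[usable]):
        idx = np.nonzero(usable & (chroms == chrom))[0]
        if idx.size < 2:
            continue
        r2 = _pairwise_r2_block(g.dosage[:, idx].T)
        pos = positions[idx]
        c = np.abs(pos[:, None] - pos[None, :]) * map_rate_cM_per_Mb / 1e8
        iu = np.triu_indices(idx.size, k=1)
        cvec = c[iu]
        rvec = r2[iu]
        ok = np.isfinite(rvec)
        which = np.searchsorted(edges, cvec[ok], side="right") - 1
        inside = (which >= 0) & (which < len(bins)) & (cvec[ok] <= edges[-1])
        np.add.at(sums, which[inside], rvec[ok][inside])
        np.add.at(counts, which[inside], 1)

    if counts.sum() == 0:
        raise ValueError("no autosomal marker pair falls in any distance bin")

    n = g.n_samples
    out: list[NeEstimate] = []
    for b, (lo, hi) in enumerate(bins):
        mid = 0.5 * (lo + hi)
        if counts[b] == 0:
            out.append(NeEstimate(lo, hi, mid, 0, float("nan"), float("nan"),
                                  float("nan")))
            continue
        mean_r2 = sums[b] / counts[b]
        adj = mean_r2 - 1.0 / (2.0 * n)
        ne = (1.0 / adj - 1.0) / (4.0 * mid) if 0.0 < adj < 1.0 else float("nan")
        out.append(NeEstimate(lo, hi, mid, int(counts[b]), float(mean_r2),
                              float(adj), float(ne)))
    return out
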