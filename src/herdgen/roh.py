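"""Runs of homozygosity and the genomic inbreeding coefficient F_ROH.

A PLINK-style scanning-window caller: a fixed-size window of
consecutive autosomal markers is declared homozygous when it contains
at most ``window_het_max`` heterozygote and ``window_missing_max``
missing calls; each marker's hit fraction is the share of homozygous
windows among the windows covering it; markers above
``window_hit_fraction`` are "in-run".  Maximal in-run stretches are
trimmed to start and end on homozygous non-missing calls, split where
adjacent markers lie further apart than ``max_gap_kb``, and filtered
by marker count, physical length and marker density.

F_ROH for a sample is the summed ROH length divided by the autosomal
genome length (by default the mapped autosomal extent of the input).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "ROHParams",
    "ROHSegment",
    "detect_roh",
    "froh",
    "roh_summaries",
    "segments_frame",
]

log = logging.getLogger(__name__)

#: Mb bin edges of the segment-length summary.
_LENGTH_BINS_MB = (1.0, 5.0, 10.0, 20.0, 40.0, float("inf"))


@dataclass(frozen=True)
class ROHParams:
    """Scanning parameters (PLINK 1.9 ``--homozyg`` defaults)."""

    window_snp: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    window_hit_fraction: float = 0.05
    min_snp: int = 100
    min_length_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    min_density_kb_per_snp: float = 50.0

    def __post_init__(self) -> None:
        if min(self.window_snp, self.window_het_max + 1, self.window_missing_max + 1,
               self.min_snp) <= 0 or min(self.window_hit_fraction, self.min_length_kb,
                                         self.max_gap_kb, self.min_density_kb_per_snp) <= 0:
            raise ValueError("all ROH parameters must be positive")


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def _chromosome_segments(dos: np.ndarray, pos: np.ndarray,
                         p: ROHParams) -> list[tuple[int, int]]:
    """In-run stretches for one sample on one chromosome, as inclusive
    (start_index, end_index) pairs after trim/split/filter."""
    m = dos.size
    w = p.window_snp
    if m < w:
        return []
    het = (dos == 1).astype(np.int64)
    mis = (dos == MISSING).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    n_windows = m - w + 1
    starts = np.arange(n_windows)
    hom_window = ((chet[starts + w] - chet[starts] <= p.window_het_max)
                  & (cmis[starts + w] - cmis[starts] <= p.window_missing_max))
    chom = np.concatenate([[0], np.cumsum(hom_window)])

    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_windows - 1)
    covering = (hi - lo + 1).astype(np.float64)
    hits = (chom[hi + 1] - chom[lo]).astype(np.float64)
    in_run = hits / covering > p.window_hit_fraction

    hom_call = (dos != 1) & (dos != MISSING)
    segments: list[tuple[int, int]] = []
    # maximal in-run stretches
    edges = np.flatnonzero(np.diff(np.concatenate([[0], in_run.view(np.int8), [0]])))
    for s, e in zip(edges[::2], edges[1::2] - 1):
        # trim ends onto homozygous non-missing calls
        while s <= e and not hom_call[s]:
            s += 1
        while e >= s and not hom_call[e]:
            e -= 1
        if s > e:
            continue
        # split at physical gaps
        gaps = np.flatnonzero(np.diff(pos[s:e + 1]) > p.max_gap_kb * 1000.0)
        pieces = []
        a = s
        for gp in gaps:
            pieces.append((a, s + gp))
            a = s + gp + 1
        pieces.append((a, e))
        for a, b in pieces:
            n_snps = b - a + 1
            length_bp = pos[b] - pos[a]
            if n_snps < p.min_snp:
                continue
            if length_bp < p.min_length_kb * 1000.0:
                continue
            if length_bp / 1000.0 / n_snps > p.min_density_kb_per_snp:
                continue
            segments.append((int(a), int(b)))
    return segments


def detect_roh(g: GenotypeMatrix, p: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Scan every sample's autosomes for runs of homozygosity.

    Non-autosomal markers (X, Y, unplaced) are excluded before
    scanning; chromosomes with fewer markers than the window size are
    skipped with a log notice.
    """
    auto_idx = np.nonzero(g.autosomal_mask())[0]
    chroms = np.array([g.markers[j].chromosome for j in auto_idx])
    positions = np.array([g.markers[j].position_bp for j in auto_idx], dtype=np.int64)

    out: list[ROHSegment] = []
    for chrom in pd.unique(chroms):
        sel = auto_idx[chroms == chrom]
        pos = positions[chroms == chrom]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"markers on chromosome {chrom} are not sorted")
        if sel.size < p.window_snp:
            log.info("chromosome %s has %d < %d markers; skipped",
                     chrom, sel.size, p.window_snp)
            continue
        block = g.dosage[:, sel]
        for i, s in enumerate(g.samples):
            for a, b in _chromosome_segments(block[i], pos, p):
                out.append(ROHSegment(sample_id=s.id, chromosome=chrom,
                                      start_bp=int(pos[a]), end_bp=int(pos[b]),
                                      n_snps=b - a + 1))
    return out


def segments_frame(segs: list[ROHSegment]) -> pd.DataFrame:
    """PLINK .hom-like table of segments."""
    return pd.DataFrame(
        [{"sample_id": s.sample_id, "chromosome": s.chromosome,
          "start_bp": s.start_bp, "end_bp": s.end_bp, "n_snps": s.n_snps,
          "length_kb": s.length_bp / 1000.0} for s in segs],
        columns=["sample_id", "chromosome", "start_bp", "end_bp",
                 "n_snps", "length_kb"])


def froh(segs: list[ROHSegment], g: GenotypeMatrix,
         autosome_length_bp: int | str = "from-map") -> pd.DataFrame:
    """Genomic inbreeding coefficient per sample.

    F_ROH = total ROH length / autosomal genome length.  With the
    default ``"from-map"`` denominator the autosome length is the
    mapped extent Σ(max position - min position) over the autosomes
    present in ``g``; samples with no segments get F_ROH = 0.
    """
    if autosome_length_bp == "from-map":
        total = 0
        chroms = np.array([m.chromosome for m in g.markers])
        pos = np.array([m.position_bp for m in g.markers], dtype=np.int64)
        auto = g.autosomal_mask()
        for chrom in pd.unique(chroms[auto]):
            cpos = pos[auto & (chroms == chrom)]
            total += int(cpos.max() - cpos.min())
        autosome_length_bp = total
    if autosome_length_bp <= 0:
        raise ValueError("autosome length must be positive")

    by_sample: dict[str, list[ROHSegment]] = {s.id: [] for s in g.samples}
    for seg in segs:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    rows = []
    for s in g.samples:
        ss = by_sample[s.id]
        tot = sum(x.length_bp for x in ss)
        rows.append({"sample_id": s.id, "n_segments": len(ss),
                     "total_roh_bp": tot,
                     "autosome_length_bp": autosome_length_bp,
                     "froh": tot / autosome_length_bp})
    return pd.DataFrame(rows).set_index("sample_id")


def roh_summaries(segs: list[ROHSegment]) -> dict[str, pd.DataFrame]:
    """Descriptive tables: segment counts per length bin and per
    chromosome, and samples per 50-Mb bin of total ROH length."""
    df = segments_frame(segs)
    lengths_mb = df["length_kb"] / 1000.0

    edges = np.array(_LENGTH_BINS_MB)
    counts, _ = np.histogram(lengths_mb, bins=edges)
    length_table = pd.DataFrame({
        "bin_low_mb": edges[:-1], "bin_high_mb": edges[1:], "count": counts})

    chrom_table = (df.groupby("chromosome").size().rename("count").reset_index()
                   if not df.empty else
                   pd.DataFrame(columns=["chromosome", "count"]))

    if df.empty:
        sample_table = pd.DataFrame(columns=["bin_low_mb", "bin_high_mb", "count"])
    else:
        totals_mb = df.groupby("sample_id")["length_kb"].sum() / 1000.0
        top = max(50.0, float(np.ceil(totals_mb.max() / 50.0) * 50.0))
        sedges = np.arange(0.0, top + 50.0, 50.0)
        scounts, _ = np.histogram(totals_mb, bins=sedges)
        sample_table = pd.DataFrame({
            "bin_low_mb": sedges[:-1], "bin_high_mb": sedges[1:], "count": scounts})

    return {"length_bins": length_table, "per_chromosome": chrom_table,
            "per_sample_total": sample_table}
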