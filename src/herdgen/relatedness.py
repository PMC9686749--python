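"""Genome-wide relationship estimation: IBS distance, VanRaden G, PCA.

The IBS genetic distance between two samples is 1 - DST, i.e. one
minus the allele-sharing similarity over markers called in both.  The
genomic relationship matrix follows VanRaden's first method:

    G = Z Z' / (2 Σ_j p_j (1 - p_j)),   Z = M - 2p

with M the dosage matrix (missing entries imputed to the marker mean
2p) and p the reference allele frequencies (in-sample by default).
Off-diagonal G entries sit on the numerator-relationship scale
(parent–offspring ≈ 0.5, half sibs ≈ 0.25), which is the scale the
family-construction kinship threshold of 0.1 operates on.

PCA is the eigendecomposition of G itself — equivalent to PCA of the
centred, frequency-scaled genotypes — with sample coordinates
eigenvector × sqrt(eigenvalue).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix
from .qc import pairwise_dst

__all__ = [
    "DistanceMatrix",
    "GMatrix",
    "PCAResult",
    "ibs_distance",
    "grm_vanraden",
    "pca",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal; NaN where undefined


@dataclass
class GMatrix:
    ids: list[str]
    values: np.ndarray
    frequencies: np.ndarray  # reference allele_b frequencies actually used
    n_markers_used: int


@dataclass
class PCAResult:
    ids: list[str]
    eigenvalues: np.ndarray          # descending
    coordinates: np.ndarray          # (n_samples, k)
    variance_explained: np.ndarray   # fractions of total positive variance


def ibs_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """IBS genetic distance d = 1 - DST over pairwise-complete markers."""
    ids, dst = pairwise_dst(g)
    d = 1.0 - dst
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=ids, values=d)


def grm_vanraden(g: GenotypeMatrix,
                 freqs: str | np.ndarray = "in-sample") -> GMatrix:
    """VanRaden (method 1) genomic relationship matrix.

    ``freqs`` is either ``"in-sample"`` (allele_b frequencies computed
    from the non-missing genotypes of ``g``) or an explicit per-marker
    array.  Markers monomorphic at the frequencies used are dropped
    from numerator and denominator alike; missing genotypes are
    mean-imputed (2p), i.e. contribute zero to Z.
    """
    valid = g.dosage != MISSING
    if isinstance(freqs, str):
        if freqs != "in-sample":
            raise ValueError(f"unknown frequency mode {freqs!r}")
        n_valid = valid.sum(axis=0).astype(np.float64)
        alt = np.where(valid, g.dosage, 0).sum(axis=0).astype(np.float64)
        with np.errstate(invalid="ignore"):
            p = alt / (2.0 * n_valid)
        p[n_valid == 0] = np.nan
    else:
        p = np.asarray(freqs, dtype=np.float64)
        if p.shape != (g.n_markers,):
            raise ValueError("frequency vector length must equal marker count")

    usable = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not usable.any():
        raise ValueError("all markers monomorphic at the stated frequencies")
    pu = p[usable]
    m = g.dosage[:, usable].astype(np.float64)
    z = np.where(valid[:, usable], m - 2.0 * pu, 0.0)
    denom = 2.0 * np.sum(pu * (1.0 - pu))
    gmat = (z @ z.T) / denom
    return GMatrix(ids=g.sample_ids, values=gmat, frequencies=p,
                   n_markers_used=int(usable.sum()))


def pca(gmat: GMatrix, k: int | None = None) -> PCAResult:
    """Top-k principal components from the eigendecomposition of G.

    Coordinates are eigenvector x sqrt(max(eigenvalue, 0)), components
    ordered by descending eigenvalue; each eigenvector's sign is fixed
    so its largest-magnitude loading is positive.
    """
    v = gmat.values
    n = v.shape[0]
    if v.shape != (n, n) or not np.allclose(v, v.T, atol=1e-8):
        raise ValueError("G matrix must be symmetric")
    if k is None:
        k = n
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    evals, evecs = np.linalg.eigh(v)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    for c in range(n):
        jmax = int(np.argmax(np.abs(evecs[:, c])))
        if evecs[jmax, c] < 0:
            evecs[:, c] = -evecs[:, c]
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))[None, :]
    pos = np.maximum(evals, 0.0)
    var_frac = (pos[:k] / pos.sum()) if pos.sum() > 0 else np.zeros(k)
    return PCAResult(ids=list(gmat.ids), eigenvalues=evals,
                     coordinates=coords, variance_explained=var_frac)
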