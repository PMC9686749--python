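"""Genotype container and PLINK-text / VCF input-output.

The in-memory model is a samples x markers matrix of alternate-allele
dosages (copies of ``allele_b``) with ``MISSING`` (-1) as the single
reserved no-call sentinel.  PED/MAP (PLINK 1.x text dialect) is the
canonical on-disk interchange format; VCF import is a read-only
convenience.

Allele coding is file-stable: ``allele_b`` is the *second* allele
observed per marker when scanning samples in file order, never the
minor allele — minor/major status can change when samples are dropped,
so frequency-dependent quantities are always computed downstream from
the dosage matrix, never baked into the coding.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MISSING",
    "AUTOSOMES",
    "Marker",
    "SampleInfo",
    "GenotypeMatrix",
    "GenotypeFormatError",
    "read_ped_map",
    "write_ped_map",
    "read_vcf",
]

#: Sentinel dosage value for a missing (no-call) genotype.
MISSING: int = -1

#: Cattle autosome labels; X, Y and "0" (unplaced) are non-autosomal classes.
AUTOSOMES: frozenset[str] = frozenset(str(c) for c in range(1, 30))

_VALID_CHROMS = AUTOSOMES | {"X", "Y", "0"}


class GenotypeFormatError(ValueError):
    """Raised for malformed PED/MAP/VCF content."""


def _chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    if chrom in AUTOSOMES:
        return (0, int(chrom), "")
    order = {"X": 0, "Y": 1, "0": 2}
    return (1, order.get(chrom, 3), chrom)


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP-array marker.

    ``chromosome`` is a string label from {1..29, X, Y, 0} (cattle
    numbering; "0" means unplaced).  ``position_bp`` is 1-based.
    ``allele_b`` may be None for a marker observed monomorphic in the
    source file.
    """

    id: str
    chromosome: str
    position_bp: int
    allele_a: str
    allele_b: str | None = None

    def __post_init__(self) -> None:
        if self.chromosome not in _VALID_CHROMS:
            raise GenotypeFormatError(
                f"marker {self.id!r}: chromosome {self.chromosome!r} not in "
                "{1..29, X, Y, 0}"
            )
        if self.position_bp < 0:
            raise GenotypeFormatError(f"marker {self.id!r}: negative position")

    @property
    def is_indel(self) -> bool:
        """True if either allele is multi-base or an I/D placeholder code."""
        for a in (self.allele_a, self.allele_b):
            if a is not None and (len(a) != 1 or a in ("I", "D")):
                return True
        return False

    @property
    def is_autosomal(self) -> bool:
        return self.chromosome in AUTOSOMES

    def sort_key(self) -> tuple:
        return (*_chrom_sort_key(self.chromosome), self.position_bp, self.id)


@dataclass(frozen=True)
class SampleInfo:
    """Sample identity and sex; call rate is computed, never read."""

    id: str
    sex: str = "unknown"  # "male" | "female" | "unknown"
    family_id: str = "0"
    sire_id: str = "0"
    dam_id: str = "0"


@dataclass
class GenotypeMatrix:
    """Samples x markers alt-allele dosage matrix with metadata.

    ``dosage[i, j]`` counts copies of ``markers[j].allele_b`` carried by
    ``samples[i]``, one of {0, 1, 2, MISSING}.  Markers are kept sorted
    by (chromosome, position, id).
    """

    samples: list[SampleInfo]
    markers: list[Marker]
    dosage: np.ndarray  # int8, shape (n_samples, n_markers)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be in {0, 1, 2, MISSING}")
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise GenotypeFormatError("duplicate sample id")
        mids = [m.id for m in self.markers]
        if len(set(mids)) != len(mids):
            raise GenotypeFormatError("duplicate marker id")
        self._sort_markers()

    def _sort_markers(self) -> None:
        order = sorted(range(len(self.markers)),
                       key=lambda j: self.markers[j].sort_key())
        if order != list(range(len(self.markers))):
            self.markers = [self.markers[j] for j in order]
            self.dosage = np.ascontiguousarray(self.dosage[:, order])

    # -- basic views -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def autosomal_mask(self) -> np.ndarray:
        return np.array([m.is_autosomal for m in self.markers], dtype=bool)

    def sample_call_rates(self) -> np.ndarray:
        """Fraction of non-missing genotypes per sample."""
        if self.n_markers == 0:
            return np.ones(self.n_samples)
        return (self.dosage != MISSING).mean(axis=1)

    def marker_call_rates(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_markers)
        return (self.dosage != MISSING).mean(axis=0)

    def subset(self,
               sample_idx: np.ndarray | list[int] | None = None,
               marker_idx: np.ndarray | list[int] | None = None
               ) -> "GenotypeMatrix":
        """Row/column subset preserving order of the retained entries."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            markers=[self.markers[j] for j in mi],
            dosage=self.dosage[np.ix_(si, mi)].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.samples == other.samples
                and self.markers == other.markers
                and np.array_equal(self.dosage, other.dosage))


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

_SEX_FROM_PED = {"1": "male", "2": "female"}
_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}


def read_ped_map(ped_path: os.PathLike | str,
                 map_path: os.PathLike | str) -> GenotypeMatrix:
    """Read PLINK text PED + MAP into a :class:`GenotypeMatrix`.

    MAP columns: CHR ID CM BP (genetic distance ignored).  PED rows:
    FID IID PAT MAT SEX PHENO then two allele columns per marker;
    "0 0" encodes a missing genotype.  Dosage counts the second allele
    observed per marker over samples in file order; heterozygote order
    within a pair is immaterial.
    """
    map_rows: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise GenotypeFormatError(
                    f"{map_path}:{lineno}: expected 4 MAP columns, got {len(parts)}")
            chrom, mid, _cm, bp = parts[:4]
            map_rows.append((chrom, mid, int(bp)))
    n_markers = len(map_rows)

    sample_rows: list[SampleInfo] = []
    allele_cols: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise GenotypeFormatError(
                    f"{ped_path}:{lineno}: fewer than 6 leading PED columns")
            fid, iid, pat, mat, sex, _pheno = parts[:6]
            alleles = parts[6:]
            if len(alleles) != 2 * n_markers:
                raise GenotypeFormatError(
                    f"{ped_path}:{lineno}: {len(alleles)} allele columns but MAP "
                    f"defines {n_markers} markers ({2 * n_markers} expected)")
            sample_rows.append(SampleInfo(
                id=iid, sex=_SEX_FROM_PED.get(sex, "unknown"),
                family_id=fid, sire_id=pat, dam_id=mat))
            allele_cols.append(alleles)

    n_samples = len(sample_rows)
    dosage = np.full((n_samples, n_markers), MISSING, dtype=np.int8)
    markers: list[Marker] = []
    for j, (chrom, mid, bp) in enumerate(map_rows):
        allele_a: str | None = None
        allele_b: str | None = None
        for i in range(n_samples):
            a1 = allele_cols[i][2 * j]
            a2 = allele_cols[i][2 * j + 1]
            if a1 == "0" or a2 == "0":
                if a1 != a2:
                    raise GenotypeFormatError(
                        f"marker {mid!r}, sample {sample_rows[i].id!r}: "
                        "half-missing genotype")
                continue
            d = 0
            for a in (a1, a2):
                if allele_a is None:
                    allele_a = a
                elif a != allele_a and allele_b is None:
                    allele_b = a
                if a == allele_b:
                    d += 1
                elif a != allele_a:
                    raise GenotypeFormatError(
                        f"marker {mid!r}: third allele {a!r} observed "
                        f"(have {allele_a!r}/{allele_b!r})")
            dosage[i, j] = d
        markers.append(Marker(id=mid, chromosome=chrom, position_bp=bp,
                              allele_a=allele_a if allele_a is not None else "A",
                              allele_b=allele_b))
    return GenotypeMatrix(samples=sample_rows, markers=markers, dosage=dosage)


def write_ped_map(g: GenotypeMatrix,
                  ped_path: os.PathLike | str,
                  map_path: os.PathLike | str) -> None:
    """Write the PED/MAP dialect :func:`read_ped_map` consumes.

    MISSING dosages become "0 0"; the MAP genetic-distance column is
    written as 0.  A write→read round trip is the identity.
    """
    with open(map_path, "w") as fh:
        for m in g.markers:
            fh.write(f"{m.chromosome}\t{m.id}\t0\t{m.position_bp}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(g.samples):
            fields = [s.family_id, s.id, s.sire_id, s.dam_id,
                      _SEX_TO_PED[s.sex], "-9"]
            row = g.dosage[i]
            for j, m in enumerate(g.markers):
                d = row[j]
                b = m.allele_b if m.allele_b is not None else m.allele_a
                if d == MISSING:
                    pair = ("0", "0")
                elif d == 0:
                    pair = (m.allele_a, m.allele_a)
                elif d == 1:
                    pair = (m.allele_a, b)
                else:
                    pair = (b, b)
                fields.extend(pair)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF (read-only convenience)
# ---------------------------------------------------------------------------

def read_vcf(vcf_path: os.PathLike | str) -> GenotypeMatrix:
    """Import biallelic GT calls from a VCF into a :class:`GenotypeMatrix`.

    0/0→0, 0/1 or 1/0→1, 1/1→2, ./.→MISSING.  Multiallelic records are
    rejected.  REF is mapped to ``allele_a`` and ALT to ``allele_b``, so
    dosage counts ALT copies; the indel flag follows allele lengths.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = [SampleInfo(id=sid) for sid in vcf.samples]
    markers: list[Marker] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise GenotypeFormatError(
                f"multiallelic record at {var.CHROM}:{var.POS} "
                f"(ALT {','.join(var.ALT)})")
        if var.gt_types is None or len(var.gt_types) != len(samples):
            raise GenotypeFormatError(
                f"record at {var.CHROM}:{var.POS} lacks GT calls")
        # gts012: 0/1/2 = ALT dosage, 3 = unknown
        col = np.asarray(var.gt_types, dtype=np.int8)
        col[col == 3] = MISSING
        chrom = var.CHROM.removeprefix("chr")
        markers.append(Marker(
            id=var.ID or f"{chrom}:{var.POS}",
            chromosome=chrom,
            position_bp=var.POS,
            allele_a=var.REF,
            allele_b=var.ALT[0]))
        columns.append(col)
    dosage = (np.stack(columns, axis=1) if columns
              else np.empty((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage)
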