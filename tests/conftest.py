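"""Shared builders for small genotype fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from herdgen.genotypes import GenotypeMatrix, Marker, SampleInfo


def make_matrix(dosage, chromosome="1", spacing_bp=10_000, sexes=None,
                chromosomes=None, positions=None):
    """GenotypeMatrix from a dosage array with evenly spaced markers."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    sexes = sexes or ["unknown"] * n
    samples = [SampleInfo(id=f"s{i + 1}", sex=sexes[i]) for i in range(n)]
    markers = []
    for j in range(m):
        markers.append(Marker(
            id=f"m{j + 1}",
            chromosome=chromosomes[j] if chromosomes else chromosome,
            position_bp=int(positions[j]) if positions is not None
            else (j + 1) * spacing_bp,
            allele_a="A", allele_b="C"))
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
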