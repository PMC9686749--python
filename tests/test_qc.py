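"""Duplicate detection, the exact HWE test, and the marker filter pass."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdgen.genotypes import MISSING
from herdgen.qc import (QCThresholds, apply_qc, find_duplicates,
                        hwe_exact_test, pairwise_dst)

from conftest import make_matrix
from oracles import hwe_exact_oracle


class TestPairwiseDst:
    def test_identical_rows(self):
        g = make_matrix([[0, 1, 2], [0, 1, 2]])
        _, d = pairwise_dst(g)
        assert d[0, 1] == 1.0

    def test_opposite_homozygotes(self):
        g = make_matrix([[0, 2], [2, 0]])
        _, d = pairwise_dst(g)
        assert d[0, 1] == 0.0

    def test_mixed_ibs(self):
        g = make_matrix([[0, 2], [0, 1]])
        _, d = pairwise_dst(g)
        assert d[0, 1] == pytest.approx(0.75)

    def test_symmetric_unit_diagonal_and_missing_sentinel(self):
        g = make_matrix([[0, MISSING], [MISSING, 2], [1, 1]])
        _, d = pairwise_dst(g)
        assert np.allclose(np.diag(d), 1.0)
        assert np.isnan(d[0, 1])  # no mutually-called marker
        assert d[0, 2] == d[2, 0]

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            pairwise_dst(make_matrix([[0, 1]]))


class TestFindDuplicates:
    def test_higher_call_rate_member_retained(self):
        row = [0, 1, 2, 1, 0] * 40
        dup = list(row)
        dup[:10] = [MISSING] * 10
        g = make_matrix([row, dup, [2] * 200])
        groups = find_duplicates(g)
        assert len(groups) == 1
        assert groups[0].retained_id == "s1"
        assert set(groups[0].members) == {"s1", "s2"}

    def test_below_threshold_not_flagged(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, 400)
        b = a.copy()
        flip = rng.choice(400, size=30, replace=False)  # ~7.5% mismatch
        b[flip] = (b[flip] + 1) % 3
        g = make_matrix([a, b])
        assert find_duplicates(g) == []

    def test_transitive_triple_keeps_one(self):
        row = [0, 1, 2, 0] * 50
        g = make_matrix([row, row, row, [2, 2, 0, 1] * 50])
        groups = find_duplicates(g)
        assert len(groups) == 1
        assert groups[0].retained_id == "s1"  # call-rate tie -> smallest id
        assert set(groups[0].members) == {"s1", "s2", "s3"}


class TestHweExact:
    @pytest.mark.parametrize("counts,expected", [
        ((1, 0, 1), 1 / 3),   # feasible het counts {0,2} with P {1/3, 2/3}
        ((0, 2, 0), 1.0),
        ((10, 0, 0), 1.0),    # monomorphic
    ])
    def test_enumerated_examples(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    @settings(max_examples=150, deadline=None)
    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    def test_matches_enumeration_oracle(self, na, h, nb):
        if na + h + nb == 0:
            return
        p = hwe_exact_test(na, h, nb)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(float(hwe_exact_oracle(na, h, nb)), abs=1e-12)


def disjoint_violation_fixture():
    """100 markers with disjoint constructed violations: 5 rare,
    3 HWE-violating, 4 low-call, 2 on X, 1 indel; 40 samples."""
    from herdgen.genotypes import GenotypeMatrix, Marker, SampleInfo
    rng = np.random.default_rng(123)
    n = 40
    cols, markers = [], []
    k = 0

    def add(col, chrom="1", alleles=("A", "C")):
        nonlocal k
        k += 1
        markers.append(Marker(f"m{k:03d}", chrom, k * 10_000,
                              alleles[0], alleles[1]))
        cols.append(np.asarray(col, dtype=np.int8))

    hwe_ok = lambda: rng.binomial(2, rng.uniform(0.3, 0.5), size=n)
    for _ in range(85):
        add(hwe_ok())
    for _ in range(5):                       # rare: monomorphic
        add(np.zeros(n))
    for _ in range(3):                       # HWE: all-homozygote split
        add(np.repeat([0, 2], [n // 2, n - n // 2]))
    for _ in range(4):                       # low call: 60% missing
        col = hwe_ok()
        col[rng.choice(n, size=24, replace=False)] = MISSING
        add(col)
    for _ in range(2):
        add(hwe_ok(), chrom="X")
    add(hwe_ok(), alleles=("I", "D"))        # indel
    dosage = np.stack(cols, axis=1)
    samples = [SampleInfo(id=f"s{i:02d}") for i in range(n)]
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage)


class TestApplyQc:
    def test_marginal_counts_match_construction(self):
        g = disjoint_violation_fixture()
        kept, rep = apply_qc(g)
        assert (rep.n_maf, rep.n_hwe, rep.n_marker_callrate, rep.n_chr_x,
                rep.n_chr_y, rep.n_chr_unplaced, rep.n_indel) == (5, 3, 4, 2, 0, 0, 1)
        assert rep.n_markers_kept == kept.n_markers == 85

    def test_maf_rule_is_strict_less_than(self):
        # 50 samples, one minor allele copy: MAF = 0.01 exactly -> retained
        col = np.zeros(50, dtype=np.int8)
        col[0] = 1
        other = np.tile([0, 1, 2, 1, 0], 10)
        g = make_matrix(np.stack([col, other], axis=1))
        kept, rep = apply_qc(g)
        assert rep.n_maf == 0
        assert kept.n_markers == 2

    def test_chromosome_x_removed_regardless(self):
        g = make_matrix([[0, 0], [1, 1], [2, 2], [1, 1]],
                        chromosomes=["1", "X"])
        kept, rep = apply_qc(g)
        assert rep.n_chr_x == 1
        assert [m.chromosome for m in kept.markers] == ["1"]

    def test_idempotent(self):
        g = disjoint_violation_fixture()
        kept1, _ = apply_qc(g)
        kept2, rep2 = apply_qc(kept1)
        assert kept2 == kept1
        assert (rep2.n_maf, rep2.n_hwe, rep2.n_marker_callrate, rep2.n_chr_x,
                rep2.n_chr_y, rep2.n_chr_unplaced, rep2.n_indel,
                len(rep2.samples_removed_duplicate)) == (0,) * 8

    def test_all_markers_removed_is_not_an_error(self):
        g = make_matrix([[0, 1], [0, 1], [0, 0]], chromosomes=["X", "Y"])
        kept, rep = apply_qc(g)
        assert kept.n_markers == 0
        assert rep.n_markers_kept == 0

    def test_sample_callrate_floor(self):
        rng = np.random.default_rng(9)
        rows = [rng.integers(0, 3, 100) for _ in range(3)]  # mutually distinct
        rows[2][:20] = MISSING  # call rate 0.8 < 0.9
        g = make_matrix(np.stack(rows))
        kept, rep = apply_qc(g)
        assert rep.samples_removed_callrate == ["s3"]
        assert kept.n_samples == 2
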