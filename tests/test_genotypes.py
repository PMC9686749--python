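"""PED/MAP and VCF reading, writing, and the coding conventions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdgen.genotypes import (MISSING, GenotypeFormatError, GenotypeMatrix,
                               Marker, SampleInfo, read_ped_map, read_vcf,
                               write_ped_map)

from conftest import make_matrix


def write_files(tmp_path, ped_lines, map_lines):
    ped = tmp_path / "x.ped"
    mp = tmp_path / "x.map"
    ped.write_text("".join(line + "\n" for line in ped_lines))
    mp.write_text("".join(line + "\n" for line in map_lines))
    return ped, mp


class TestReadPedMap:
    def test_dosage_counts_second_observed_allele(self, tmp_path):
        ped, mp = write_files(
            tmp_path,
            ["0 sample1 0 0 1 -9 A A G G",
             "0 sample2 0 0 2 -9 A C G G"],
            ["1 m1 0 100", "1 m2 0 200"])
        g = read_ped_map(ped, mp)
        assert np.array_equal(g.dosage, [[0, 0], [1, 0]])
        assert g.markers[0].allele_a == "A" and g.markers[0].allele_b == "C"
        assert g.markers[1].allele_b is None  # monomorphic
        assert [s.sex for s in g.samples] == ["male", "female"]

    def test_zero_pair_is_missing(self, tmp_path):
        ped, mp = write_files(
            tmp_path,
            ["0 a 0 0 0 -9 A A G G", "0 b 0 0 0 -9 0 0 G T"],
            ["1 m1 0 100", "1 m2 0 200"])
        g = read_ped_map(ped, mp)
        assert g.dosage[1, 0] == MISSING
        assert (g.dosage != MISSING).sum() == 3

    def test_heterozygote_order_irrelevant(self, tmp_path):
        ped1, mp1 = write_files(tmp_path, ["0 a 0 0 0 -9 A C", "0 b 0 0 0 -9 C A"],
                                ["1 m1 0 100"])
        g = read_ped_map(ped1, mp1)
        assert g.dosage[0, 0] == g.dosage[1, 0] == 1

    def test_column_count_mismatch_names_both_counts(self, tmp_path):
        ped, mp = write_files(tmp_path, ["0 a 0 0 0 -9 A A C C G G"],
                              ["1 m1 0 100", "1 m2 0 200"])
        with pytest.raises(GenotypeFormatError, match="6.*2"):
            read_ped_map(ped, mp)

    def test_third_allele_names_marker(self, tmp_path):
        ped, mp = write_files(
            tmp_path,
            ["0 a 0 0 0 -9 A A", "0 b 0 0 0 -9 A C", "0 c 0 0 0 -9 G G"],
            ["1 bad1 0 100"])
        with pytest.raises(GenotypeFormatError, match="bad1"):
            read_ped_map(ped, mp)

    def test_duplicate_ids_rejected(self, tmp_path):
        ped, mp = write_files(tmp_path, ["0 a 0 0 0 -9 A A", "0 a 0 0 0 -9 A A"],
                              ["1 m1 0 100"])
        with pytest.raises(GenotypeFormatError, match="duplicate sample"):
            read_ped_map(ped, mp)
        ped, mp = write_files(tmp_path, ["0 a 0 0 0 -9 A A C C"],
                              ["1 m1 0 100", "1 m1 0 200"])
        with pytest.raises(GenotypeFormatError, match="duplicate marker"):
            read_ped_map(ped, mp)


class TestWritePedMap:
    def test_missing_encoded_as_zero_pair(self, tmp_path):
        g = make_matrix([[0, 1], [MISSING, 2]])
        write_ped_map(g, tmp_path / "o.ped", tmp_path / "o.map")
        zero_pairs = 0
        for line in (tmp_path / "o.ped").read_text().splitlines():
            alleles = line.split("\t")[6:]
            zero_pairs += sum(alleles[2 * j:2 * j + 2] == ["0", "0"]
                              for j in range(len(alleles) // 2))
        assert zero_pairs == 1

    def test_empty_cohort(self, tmp_path):
        g = GenotypeMatrix(
            samples=[],
            markers=[Marker("m1", "1", 100, "A", "C")],
            dosage=np.empty((0, 1), dtype=np.int8))
        write_ped_map(g, tmp_path / "o.ped", tmp_path / "o.map")
        assert (tmp_path / "o.ped").read_text() == ""
        assert len((tmp_path / "o.map").read_text().splitlines()) == 1

    def test_round_trip_identity(self, tmp_path):
        g = make_matrix([[0, 1, 2, MISSING], [1, 1, 0, 2], [2, MISSING, 0, 0]],
                        sexes=["male", "female", "unknown"])
        write_ped_map(g, tmp_path / "a.ped", tmp_path / "a.map")
        g1 = read_ped_map(tmp_path / "a.ped", tmp_path / "a.map")
        # one pass canonicalises the allele coding; after that the
        # write→read round trip is the exact identity
        write_ped_map(g1, tmp_path / "b.ped", tmp_path / "b.map")
        g2 = read_ped_map(tmp_path / "b.ped", tmp_path / "b.map")
        assert g2 == g1


@st.composite
def small_matrices(draw):
    n = draw(st.integers(1, 5))
    m = draw(st.integers(1, 6))
    cells = draw(st.lists(
        st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=m, max_size=m),
        min_size=n, max_size=n))
    return make_matrix(cells)


@settings(max_examples=60, deadline=None)
@given(g=small_matrices())
def test_round_trip_preserves_genotypes(g, tmp_path_factory):
    """write→read keeps every genotype (up to the documented recoding
    onto second-observed-allele coding) and is idempotent thereafter."""
    tmp = tmp_path_factory.mktemp("rt")
    write_ped_map(g, tmp / "a.ped", tmp / "a.map")
    g1 = read_ped_map(tmp / "a.ped", tmp / "a.map")
    assert [s.id for s in g1.samples] == [s.id for s in g.samples]
    assert [m.id for m in g1.markers] == [m.id for m in g.markers]
    for j in range(g.n_markers):
        a, b = g.dosage[:, j], g1.dosage[:, j]
        flipped = np.where(b == MISSING, MISSING, 2 - b)
        assert np.array_equal(a, b) or np.array_equal(a, flipped)
    write_ped_map(g1, tmp / "b.ped", tmp / "b.map")
    assert read_ped_map(tmp / "b.ped", tmp / "b.map") == g1


class TestReadVcf:
    HEADER = ("##fileformat=VCFv4.2\n"
              "##FORMAT=<ID=GT,Number=1,Type=String,Description=\"Genotype\">\n"
              "##contig=<ID=1>\n"
              "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n")

    def write_vcf(self, tmp_path, records):
        path = tmp_path / "t.vcf"
        path.write_text(self.HEADER + "".join(r + "\n" for r in records))
        return path

    def test_gt_coding(self, tmp_path):
        path = self.write_vcf(tmp_path, [
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1",
            "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t./.\t1/0\t0/0"])
        g = read_vcf(path)
        assert np.array_equal(g.dosage[:, 0], [0, 1, 2])
        assert g.dosage[0, 1] == MISSING and g.dosage[1, 1] == 1

    def test_indel_flag_from_allele_length(self, tmp_path):
        path = self.write_vcf(tmp_path,
                              ["1\t100\trs1\tA\tAT\t.\t.\t.\tGT\t0/0\t0/1\t1/1"])
        g = read_vcf(path)
        assert g.markers[0].is_indel

    def test_multiallelic_rejected(self, tmp_path):
        path = self.write_vcf(tmp_path,
                              ["1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1\t1/1"])
        with pytest.raises(GenotypeFormatError, match="100"):
            read_vcf(path)


class TestModel:
    def test_markers_sorted_by_chromosome_then_position(self):
        g = make_matrix([[0, 1, 2]], chromosomes=["2", "1", "1"],
                        positions=[100, 500, 100])
        assert [m.chromosome for m in g.markers] == ["1", "1", "2"]
        assert [m.position_bp for m in g.markers] == [100, 500, 100]
        assert np.array_equal(g.dosage, [[2, 1, 0]])

    def test_indel_rule(self):
        assert Marker("m", "1", 1, "A", "AT").is_indel
        assert Marker("m", "1", 1, "I", "D").is_indel
        assert not Marker("m", "1", 1, "A", "C").is_indel

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError, match="dosage"):
            make_matrix([[0, 5]])

    def test_call_rates(self):
        g = make_matrix([[0, MISSING, 2, 1], [MISSING, MISSING, 0, 0]])
        assert np.allclose(g.sample_call_rates(), [0.75, 0.5])
        assert np.allclose(g.marker_call_rates(), [0.5, 0.0, 1.0, 1.0])
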