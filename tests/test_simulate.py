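"""Cohort generator: determinism, pedigree truth, artifact classes."""

import numpy as np
import pytest

from herdgen.genotypes import MISSING
from herdgen.qc import hwe_exact_test
from herdgen.simulate import (MatingRecord, SimulationConfig,
                              default_study_config, pedigree_inbreeding,
                              simulate_cohort, write_fixture)


def founder_config(seed=1, n=30, **kw):
    founders = [(f"F{i}", "male" if i < 5 else "female") for i in range(n)]
    defaults = dict(n_chromosomes=3, chromosome_length_bp=10_000_000,
                    markers_per_chromosome=150)
    defaults.update(kw)
    return SimulationConfig(seed=seed, founders=founders, **defaults)


class TestDeterminism:
    def test_same_seed_same_fixture_bytes(self, tmp_path):
        cfg = founder_config(seed=7, n_duplicate_pairs=1, missing_rate=0.03,
                             n_rare_markers=2, n_x_markers=2)
        for d in ("a", "b"):
            g, t = simulate_cohort(cfg)
            write_fixture(g, t, tmp_path / d)
        for name in ("cohort.ped", "cohort.map", "sample_truth.tsv",
                     "marker_truth.tsv", "duplicate_pairs.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_seed_changes_genotypes_not_shapes(self):
        g1, _ = simulate_cohort(founder_config(seed=1))
        g2, _ = simulate_cohort(founder_config(seed=2))
        assert g1.dosage.shape == g2.dosage.shape
        assert not np.array_equal(g1.dosage, g2.dosage)


class TestPedigreeTruth:
    def test_full_sib_mating_offspring_f_quarter(self):
        founders = [("f", "male"), ("m", "female")]
        ped = [MatingRecord("f", "m", "s1", "male"),
               MatingRecord("f", "m", "s2", "female"),
               MatingRecord("s1", "s2", "kid", "female")]
        f = pedigree_inbreeding([x for x, _ in founders], ped)
        assert f["kid"] == pytest.approx(0.25)
        assert f["s1"] == 0.0

    def test_half_sib_and_self_lineage_values(self):
        founders = [("s", "male"), ("d1", "female"), ("d2", "female")]
        ped = [MatingRecord("s", "d1", "h1", "female"),
               MatingRecord("s", "d2", "h2", "male"),
               MatingRecord("h2", "h1", "kid", "female")]
        f = pedigree_inbreeding([x for x, _ in founders], ped)
        assert f["kid"] == pytest.approx(0.125)  # half-sib mating

    def test_truth_table_carries_f_ped(self):
        founders = [("f", "male"), ("m", "female")]
        ped = [MatingRecord("f", "m", "s1", "male"),
               MatingRecord("f", "m", "s2", "female"),
               MatingRecord("s1", "s2", "kid", "female")]
        cfg = SimulationConfig(seed=3, founders=founders, pedigree=ped,
                               n_chromosomes=2, chromosome_length_bp=5_000_000,
                               markers_per_chromosome=50)
        _, t = simulate_cohort(cfg)
        truth = t.samples.set_index("sample_id")
        assert truth.loc["kid", "f_ped"] == pytest.approx(0.25)


class TestArtifacts:
    def test_duplicate_rows_identical_before_missingness(self):
        cfg = founder_config(seed=9, n_duplicate_pairs=2, missing_rate=0.0)
        g, t = simulate_cohort(cfg)
        assert len(t.duplicate_pairs) == 2
        idx = {s: i for i, s in enumerate(g.sample_ids)}
        for orig, dup in t.duplicate_pairs:
            assert np.array_equal(g.dosage[idx[orig]], g.dosage[idx[dup]])

    def test_marker_truth_partitions_markers(self):
        cfg = founder_config(seed=4, n_rare_markers=3, n_hwe_violating_markers=2,
                             n_x_markers=2, n_y_markers=1, n_unplaced_markers=2,
                             n_indel_markers=1, n_low_call_markers=2,
                             founder_maf_range=(0.25, 0.45))
        g, t = simulate_cohort(cfg)
        assert len(t.markers) == g.n_markers
        assert list(t.markers["marker_id"]) == g.marker_ids
        counts = t.markers["qc_class"].value_counts()
        assert counts["clean"] == 450
        assert (counts["rare"], counts["hwe"], counts["chrX"], counts["chrY"],
                counts["unplaced"], counts["indel"], counts["low_call"]) == \
            (3, 2, 2, 1, 2, 1, 2)

    def test_injected_hwe_markers_fail_the_exact_test(self):
        cfg = founder_config(seed=5, n_hwe_violating_markers=4)
        g, t = simulate_cohort(cfg)
        hwe_ids = set(t.markers.loc[t.markers["qc_class"] == "hwe", "marker_id"])
        for j, m in enumerate(g.markers):
            if m.id in hwe_ids:
                counts = np.bincount(g.dosage[:, j], minlength=3)
                assert hwe_exact_test(*(int(c) for c in counts[:3])) < 1e-6

    def test_rare_markers_are_monomorphic(self):
        cfg = founder_config(seed=6, n_rare_markers=5)
        g, t = simulate_cohort(cfg)
        rare = set(t.markers.loc[t.markers["qc_class"] == "rare", "marker_id"])
        for j, m in enumerate(g.markers):
            if m.id in rare:
                assert (g.dosage[:, j] == 0).all()


class TestNeutralStatistics:
    def test_founder_heterozygosity_matches_maf_law(self):
        cfg = founder_config(seed=8, n=200, markers_per_chromosome=400,
                             founder_maf_range=(0.05, 0.5))
        g, _ = simulate_cohort(cfg)
        ho = (g.dosage == 1).mean()
        p = np.linspace(0.05, 0.5, 2001)
        expected = np.mean(2 * p * (1 - p))
        assert ho == pytest.approx(expected, abs=0.01)

    def test_neutral_cohort_rarely_rejects_hwe(self):
        cfg = founder_config(seed=12, n=60, markers_per_chromosome=500)
        g, _ = simulate_cohort(cfg)
        n_reject = 0
        for j in range(g.n_markers):
            counts = np.bincount(g.dosage[:, j], minlength=3)
            if hwe_exact_test(*(int(c) for c in counts[:3])) < 1e-6:
                n_reject += 1
        assert n_reject <= max(2, int(0.001 * g.n_markers))


class TestConfigValidation:
    def test_unknown_pedigree_parent(self):
        with pytest.raises(ValueError, match="unknown parent"):
            SimulationConfig(seed=1, founders=[("a", "male")],
                             pedigree=[MatingRecord("a", "ghost", "k", "male")],
                             ).validate()

    def test_zero_budget_with_artifacts(self):
        with pytest.raises(ValueError, match="zero clean-marker budget"):
            founder_config(markers_per_chromosome=0, n_rare_markers=3).validate()

    def test_negative_counts(self):
        with pytest.raises(ValueError):
            founder_config(n_x_markers=-1).validate()

    def test_hwe_decoys_impossible_in_tiny_cohorts(self):
        cfg = founder_config(n=3, n_hwe_violating_markers=1)
        with pytest.raises(RuntimeError, match="too small"):
            simulate_cohort(cfg)


def test_default_study_config_shape():
    cfg = default_study_config(0)
    cfg.validate()
    assert len(cfg.sampled_ids) == 44  # + 2 duplicate copies = 46 genotyped
    sexes = dict(cfg.founders)
    males = [s for s in cfg.sampled_ids if s.startswith("B")]
    assert len(males) == 9
    assert cfg.n_chromosomes == 29
    total = (cfg.n_chromosomes * cfg.markers_per_chromosome + cfg.n_x_markers
             + cfg.n_y_markers + cfg.n_unplaced_markers + cfg.n_indel_markers
             + cfg.n_rare_markers + cfg.n_hwe_violating_markers
             + cfg.n_low_call_markers)
    assert total == 101_209
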