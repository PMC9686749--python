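"""End-to-end analysis pipeline: QC → diversity → ROH → kinship → families.

One configuration drives the full herd analysis and produces a report
bundle of TSV tables and Newick trees mirroring the sections of a
conservation-genetics study: a QC audit table, a diversity summary
with MAF/PIC histograms and per-bin Ne estimates, ROH segments and
F_ROH per animal, IBS and G matrices with PCA coordinates, NJ trees
(all animals, bulls only) and the family table.

Runs are deterministic: the same inputs and configuration produce a
byte-identical bundle, and the manifest records package version,
configuration echo and input checksums so any run can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .diversity import (cohort_diversity, default_ne_bins, estimate_ne,
                        individual_heterozygosity, marker_stats)
from .families import build_families, nj_tree, to_newick
from .genotypes import GenotypeMatrix, read_ped_map, read_vcf
from .qc import QCReport, QCThresholds, apply_qc
from .relatedness import DistanceMatrix, grm_vanraden, ibs_distance, pca
from .roh import ROHParams, detect_roh, froh, roh_summaries, segments_frame

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    ped_path: str | None = None
    map_path: str | None = None
    vcf_path: str | None = None
    out_dir: str = "herdgen_out"
    qc: QCThresholds = field(default_factory=QCThresholds)
    roh: ROHParams = field(default_factory=ROHParams)
    ne_bins: list[tuple[float, float]] = field(default_factory=default_ne_bins)
    map_rate_cM_per_Mb: float = 1.0
    kinship_threshold: float = 0.1
    autosome_length_bp: int | str = "from-map"


@dataclass
class ReportBundle:
    """In-memory results plus the paths of everything written."""

    genotypes: GenotypeMatrix
    qc_report: QCReport
    diversity: object
    froh: pd.DataFrame
    ibs: DistanceMatrix
    grm: object
    families: object
    files: dict[str, str]


def _write_matrix(ids: list[str], values: np.ndarray, path: str) -> None:
    pd.DataFrame(values, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format="%.8g", index_label="sample_id")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load(cfg: PipelineConfig) -> tuple[GenotypeMatrix, dict[str, str]]:
    if cfg.vcf_path:
        return read_vcf(cfg.vcf_path), {"vcf": _sha256(cfg.vcf_path)}
    if not (cfg.ped_path and cfg.map_path):
        raise ValueError("either ped_path+map_path or vcf_path is required")
    g = read_ped_map(cfg.ped_path, cfg.map_path)
    return g, {"ped": _sha256(cfg.ped_path), "map": _sha256(cfg.map_path)}


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute every stage in order and write the report bundle."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    files: dict[str, str] = {}

    def out(name: str) -> str:
        path = os.path.join(cfg.out_dir, name)
        files[name] = path
        return path

    timings: list[tuple[str, float]] = []

    def stage(name: str):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s started", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings.append((name, time.perf_counter() - self.t0))
                if exc_type is not None:
                    log.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                log.info("stage %s done", name)
                return False
        return _T()

    with stage("load"):
        g_raw, checksums = _load(cfg)

    with stage("qc"):
        g, qc_report = apply_qc(g_raw, cfg.qc)
        with open(out("qc_report.txt"), "w") as fh:
            fh.write(qc_report.to_text())
        pd.DataFrame({
            "rule": ["total", "maf", "hwe", "marker_callrate", "chrX", "chrY",
                     "chr0", "indel", "kept"],
            "count": [qc_report.n_markers_total, qc_report.n_maf, qc_report.n_hwe,
                      qc_report.n_marker_callrate, qc_report.n_chr_x,
                      qc_report.n_chr_y, qc_report.n_chr_unplaced,
                      qc_report.n_indel, qc_report.n_markers_kept],
        }).to_csv(out("qc_report.tsv"), sep="\t", index=False)
        if g.n_markers == 0 or g.n_samples == 0:
            log.warning("QC removed everything; downstream stages skipped")

    # PN is computed on the post-sample-QC, pre-marker-QC marker set:
    # on the post-marker-QC set every survivor is polymorphic by
    # construction and PN would be identically 1.
    with stage("diversity"):
        pre_marker_qc = g_raw.subset(
            sample_idx=[i for i, s in enumerate(g_raw.samples)
                        if s.id in set(g.sample_ids)])
        stats_pre = marker_stats(pre_marker_qc, maf_min=cfg.qc.maf_min)
        stats_post = marker_stats(g, maf_min=cfg.qc.maf_min)
        try:
            ne = estimate_ne(g, bins=cfg.ne_bins,
                             map_rate_cM_per_Mb=cfg.map_rate_cM_per_Mb,
                             maf_min=cfg.qc.maf_min)
        except ValueError:
            ne = []
        div = cohort_diversity(stats_pre, ne_estimates=ne)
        # cohort means besides PN are reported on the QC-surviving markers
        div_post = cohort_diversity(stats_post, ne_estimates=ne)
        div_post.pn = div.pn
        summary = div_post.to_frame()
        summary.loc["Proportion of Polymorphic Markers (PN)", "value"] = div.pn
        summary.to_csv(out("diversity.tsv"), sep="\t", float_format="%.6g",
                       index_label="statistic")
        div_post.maf_histogram.to_csv(out("maf_histogram.tsv"), sep="\t",
                                      index=False, float_format="%.6g")
        div_post.pic_histogram.to_csv(out("pic_histogram.tsv"), sep="\t",
                                      index=False, float_format="%.6g")
        individual_heterozygosity(g).to_csv(out("individual_ho.tsv"), sep="\t",
                                            float_format="%.6g")
        pd.DataFrame([{"c_low": e.c_low, "c_high": e.c_high, "c_mid": e.c_mid,
                       "n_pairs": e.n_pairs, "mean_r2": e.mean_r2,
                       "mean_r2_adj": e.mean_r2_adj, "ne": e.ne} for e in ne]) \
            .to_csv(out("ne_estimates.tsv"), sep="\t", index=False,
                    float_format="%.6g")

    with stage("roh"):
        segs = detect_roh(g, cfg.roh)
        segments_frame(segs).to_csv(out("roh_segments.tsv"), sep="\t",
                                    index=False, float_format="%.6g")
        for name, table in roh_summaries(segs).items():
            table.to_csv(out(f"roh_{name}.tsv"), sep="\t", index=False,
                         float_format="%.6g")
        froh_table = froh(segs, g, cfg.autosome_length_bp)
        froh_table.to_csv(out("froh.tsv"), sep="\t", float_format="%.8g")

    with stage("relatedness"):
        ibs = ibs_distance(g)
        _write_matrix(ibs.ids, ibs.values, out("ibs_matrix.tsv"))
        gmat = grm_vanraden(g)
        _write_matrix(gmat.ids, gmat.values, out("grm.tsv"))
        pcs = pca(gmat, k=min(10, g.n_samples))
        coords = pd.DataFrame(
            pcs.coordinates, index=pcs.ids,
            columns=[f"PC{i + 1}" for i in range(pcs.coordinates.shape[1])])
        coords.to_csv(out("pca_coordinates.tsv"), sep="\t",
                      float_format="%.8g", index_label="sample_id")
        pd.DataFrame({"eigenvalue": pcs.eigenvalues,
                      "variance_explained": np.pad(
                          pcs.variance_explained,
                          (0, len(pcs.eigenvalues) - len(pcs.variance_explained)),
                          constant_values=np.nan)}) \
            .to_csv(out("pca_eigenvalues.tsv"), sep="\t", index=False,
                    float_format="%.8g")

    with stage("clustering"):
        if g.n_samples >= 3:
            with open(out("tree_all.nwk"), "w") as fh:
                fh.write(to_newick(nj_tree(ibs)) + "\n")
        bull_ids = [s.id for s in g.samples if s.sex == "male"]
        if len(bull_ids) >= 3:
            bidx = [i for i, s in enumerate(g.samples) if s.sex == "male"]
            sub = DistanceMatrix(ids=bull_ids,
                                 values=ibs.values[np.ix_(bidx, bidx)])
            with open(out("tree_bulls.nwk"), "w") as fh:
                fh.write(to_newick(nj_tree(sub)) + "\n")

    with stage("families"):
        sex = {s.id: s.sex for s in g.samples}
        fam = build_families(gmat, sex, threshold=cfg.kinship_threshold)
        rows = []
        for label, bulls, cows in fam.families:
            rows += [{"family": label, "role": "bull", "sample_id": b} for b in bulls]
            rows += [{"family": label, "role": "cow", "sample_id": c} for c in cows]
        rows += [{"family": "other", "role": "cow", "sample_id": c}
                 for c in fam.other]
        pd.DataFrame(rows, columns=["family", "role", "sample_id"]) \
            .to_csv(out("families.tsv"), sep="\t", index=False)

    with stage("manifest"):
        manifest = {
            "herdgen_version": __version__,
            "config": {
                "ped_path": cfg.ped_path, "map_path": cfg.map_path,
                "vcf_path": cfg.vcf_path,
                "qc": asdict(cfg.qc), "roh": asdict(cfg.roh),
                "ne_bins": cfg.ne_bins,
                "map_rate_cM_per_Mb": cfg.map_rate_cM_per_Mb,
                "kinship_threshold": cfg.kinship_threshold,
                "autosome_length_bp": cfg.autosome_length_bp,
            },
            "input_checksums_sha256": checksums,
            "n_samples_input": g_raw.n_samples,
            "n_markers_input": g_raw.n_markers,
            "n_samples_after_qc": g.n_samples,
            "n_markers_after_qc": g.n_markers,
        }
        with open(out("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    for name, dt in timings:
        log.info("stage %-12s %.2fs", name, dt)

    return ReportBundle(genotypes=g, qc_report=qc_report, diversity=div_post,
                        froh=froh_table, ibs=ibs, grm=gmat, families=fam,
                        files=files)
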