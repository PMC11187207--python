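"""End-to-end pipeline: simulate -> QC -> RT -> CNV/breaks -> enrichment.

Configuration is a flat key-value mapping (YAML on disk) validated
before any stage runs; every random operation receives an explicit
seed, and a rerun with an identical config is byte-identical for all
TSV/BED/bedGraph outputs. Each stage can also be run independently on
the previous stage's files (see :mod:`embryort.cli`).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cnv import CopyNumberModel
from .enrich import (
    DEFAULT_NULL_SITES,
    enrichment_test,
    lamina_oe,
    sample_random_regions,
    value_at_sites,
)
from .errors import InvalidArgumentError
from .genome import IntervalTrack, bin_track, partition_genome, write_bed, write_bedgraph
from .qc import qc_cells, qc_table
from .rt import ReplicationTimingModel
from .simulate import default_genome, inject_cn_event, make_rt_truth, simulate_cells

log = logging.getLogger("embryort")

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline parameters; defaults mirror the analysis conventions
    (100 kb RT/CNV bins, MAD phase thresholds, |dCN| > 1 break rule,
    50 % early/late rule, 2.59 kb/um fiber conversion)."""

    out_dir: str = "embryort_out"
    seed: int = 7

    # simulation (ignored when counts_path is given)
    counts_path: str | None = None
    reference_path: str | None = None  # counts TSV of an external G1 cohort
    n_reference: int = 30  # simulated G1 reference cohort size
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 100_000_000, "chr2": 100_000_000})
    bin_size: int = 100_000
    correlation_length_bins: int = 20
    coupling: float = 2.0
    n_g1: int = 30
    n_s: int = 150
    mean_reads_per_cell: int = 1_000_000
    nb_dispersion: float = 10.0
    amp_noise_sd: float = 0.1
    gc_coeff: float = 0.3
    flip_rate: float = 0.02
    f_min: float = 0.05
    f_max: float = 0.95
    inject_events: list = field(default_factory=list)  # dicts: cell_id, chrom[, start, end], delta_cn

    # QC
    qc_span: float = 0.25
    calibrate_thresholds: bool = True
    g1_max: float = 0.3
    s_min: float = 0.4
    s_max: float = 0.8

    # RT
    min_sep: float = 0.3
    min_bins: int = 100

    # CNV / breaks
    min_seg_bins: int = 5
    penalty: float = 3.0
    baseline_cn: int = 2
    min_delta_cn: float = 1.0

    # enrichment
    n_null: int = DEFAULT_NULL_SITES

    def validate(self) -> None:
        checks = [
            (self.bin_size > 0, "bin_size must be positive"),
            (0 <= self.flip_rate < 0.5, "flip_rate must be in [0, 0.5)"),
            (0 < self.f_min < self.f_max < 1, "need 0 < f_min < f_max < 1"),
            (self.min_sep > 0, "min_sep must be positive"),
            (self.min_seg_bins >= 1, "min_seg_bins must be >= 1"),
            (self.penalty >= 0, "penalty must be >= 0"),
            (self.min_delta_cn >= 0, "min_delta_cn must be >= 0"),
            (self.n_null >= 1, "n_null must be >= 1"),
            (0 <= self.g1_max <= self.s_min <= self.s_max, "need 0 <= g1_max <= s_min <= s_max"),
        ]
        for ok, msg in checks:
            if not ok:
                raise InvalidArgumentError(f"config: {msg}")
        if self.counts_path is not None and not Path(self.counts_path).exists():
            raise InvalidArgumentError(f"config: counts_path {self.counts_path!r} does not exist")


def load_config(path=None, **overrides) -> PipelineConfig:
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(PipelineConfig.__dataclass_fields__)
        if unknown:
            raise InvalidArgumentError(f"config: unknown keys {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


class _Stage:
    """Context manager logging stage duration to stderr."""

    def __init__(self, name):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is None:
            log.info("stage %s: done in %.1fs", self.name, dt)
        else:
            log.error("stage %s: failed after %.1fs: %s", self.name, dt, exc)
        return False


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a report dict with paths and key counts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not logging.getLogger().handlers and not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")

    report: dict = {"version": __version__, "config": asdict(config), "outputs": {}}

    # --- simulate (or load) ------------------------------------------------
    with _Stage("simulate"):
        reference_counts = None
        if config.counts_path is not None:
            counts_df = pd.read_csv(config.counts_path, sep="\t", index_col=0)
            bins = _bins_from_columns(counts_df.columns, config.bin_size)
            counts = counts_df.to_numpy(dtype=np.int64)
            cell_ids = list(counts_df.index.astype(str))
            truth = None
            sim = None
            if config.reference_path is not None:
                reference_counts = pd.read_csv(
                    config.reference_path, sep="\t", index_col=0
                ).to_numpy(dtype=np.int64)
        else:
            bins = default_genome(config.bin_size, seed=config.seed)
            if dict(config.chrom_lengths) != dict(bins.chrom_lengths):
                bins = partition_genome(config.chrom_lengths, config.bin_size)
                bins = default_genome_gc(bins, config.seed)
            truth = make_rt_truth(
                bins, config.correlation_length_bins, config.coupling, seed=config.seed
            )
            sim = simulate_cells(
                truth,
                n_g1=config.n_g1,
                n_s=config.n_s,
                mean_reads_per_cell=config.mean_reads_per_cell,
                nb_dispersion=config.nb_dispersion,
                amp_noise_sd=config.amp_noise_sd,
                gc_coeff=config.gc_coeff,
                flip_rate=config.flip_rate,
                f_range=(config.f_min, config.f_max),
                seed=config.seed + 1,
            )
            for i, ev in enumerate(config.inject_events):
                region = (
                    ev["chrom"]
                    if "start" not in ev
                    else (ev["chrom"], int(ev["start"]), int(ev["end"]))
                )
                sim = inject_cn_event(
                    sim, ev["cell_id"], region, int(ev["delta_cn"]), seed=config.seed + 100 + i
                )
            counts, cell_ids = sim.counts, sim.cell_ids
            # dedicated non-replicating reference cohort, the synthetic
            # analogue of an external G1 ES-cell reference dataset
            ref_sim = simulate_cells(
                truth,
                n_g1=config.n_reference,
                n_s=0,
                mean_reads_per_cell=config.mean_reads_per_cell,
                nb_dispersion=config.nb_dispersion,
                amp_noise_sd=config.amp_noise_sd,
                gc_coeff=config.gc_coeff,
                flip_rate=0.0,
                f_range=(config.f_min, config.f_max),
                seed=config.seed + 2,
            )
            reference_counts = ref_sim.counts
            ref_sim.write_tsv(out / "reference_counts.tsv")
            sim.write_tsv(out / "counts.tsv", out / "truth.tsv")
            write_bed(truth.lad_track(), out / "lads.bed")
            write_bed(truth.origins, out / "origins.bed")
            write_bed(truth.genes, out / "genes.bed")
            write_bedgraph(truth.compartment, bins, out / "compartment.bedgraph")
            write_bedgraph(truth.t, bins, out / "rt_truth.bedgraph")
            if bins.gc is not None:
                write_bedgraph(bins.gc, bins, out / "gc.bedgraph")
        log.info("cells: %d, bins: %d", len(cell_ids), bins.n_bins)

    # --- QC ----------------------------------------------------------------
    with _Stage("qc"):
        from .qc import PhaseThresholds

        thresholds = (
            None
            if config.calibrate_thresholds
            else PhaseThresholds(config.g1_max, config.s_min, config.s_max)
        )
        profiles = qc_cells(
            counts, cell_ids, bins,
            reference_counts=reference_counts,
            thresholds=thresholds, span=config.qc_span,
            calibrate=config.calibrate_thresholds,
        )
        table = qc_table(profiles)
        table.to_csv(out / "qc.tsv", sep="\t", index=False, float_format="%.6g")
        ratio_df = pd.DataFrame(
            np.vstack([p.copy_ratio for p in profiles]), index=cell_ids
        )
        ratio_df.to_csv(out / "ratios.tsv", sep="\t", float_format="%.6g", index_label="cell_id")
        n_s = int((table["phase"] == "S").sum())
        n_g1 = int((table["phase"] == "G1").sum())
        log.info("phases: %d G1, %d S, %d excluded", n_g1, n_s, len(table) - n_g1 - n_s)

    # --- RT ----------------------------------------------------------------
    with _Stage("rt"):
        s_cells = [p for p in profiles if p.phase == "S"]
        rt_res = None
        if s_cells:
            model = ReplicationTimingModel(
                {p.cell_id: p.copy_ratio for p in s_cells}, bins,
                min_sep=config.min_sep, min_bins=config.min_bins,
            )
            rt_res = model.fit()
            rt_res.to_bedgraph(out / "rt_profile.bedgraph")
            rt_res.classes_bed(out / "rt_classes.bed")
            rt_res.binary_table().to_csv(
                out / "binary_matrix.tsv", sep="\t", float_format="%.0f", index_label="cell_id"
            )
            log.info(
                "informative S cells: %d (%d dropped); early/late/boundary: %s",
                len(rt_res.binary), len(rt_res.non_informative),
                rt_res.aggregate.class_counts(),
            )

    # --- CNV / breaks -------------------------------------------------------
    with _Stage("breaks"):
        cn_model = CopyNumberModel(
            {p.cell_id: p.copy_ratio for p in profiles if p.phase != "S"},
            bins,
            min_seg_bins=config.min_seg_bins,
            penalty=config.penalty,
            baseline_cn=config.baseline_cn,
        ) if any(p.phase != "S" for p in profiles) else None
        # CNV calling is most reliable on flat (G1/excluded) profiles; S cells
        # carry replication-driven 1x/2x structure that mimics CN changes.
        if cn_model is None:
            cn_model = CopyNumberModel(
                {p.cell_id: p.copy_ratio for p in profiles}, bins,
                min_seg_bins=config.min_seg_bins, penalty=config.penalty,
                baseline_cn=config.baseline_cn,
            )
        cn_res = cn_model.fit()
        cn_res.segments_tsv(out / "segments.tsv")
        cn_res.breakpoints_bed(out / "breaksites.bed", min_delta=config.min_delta_cn)
        karyo = cn_res.karyotype_summary()
        karyo.calls.to_csv(out / "karyotype.tsv", sep="\t", index=False)
        breaks = cn_res.breakpoints(min_delta=config.min_delta_cn)
        log.info("break sites: %d; aneuploidy fraction: %.3f", len(breaks), karyo.aneuploidy_fraction)

    # --- enrichment ---------------------------------------------------------
    with _Stage("enrich"):
        rows = []
        if truth is not None and rt_res is not None:
            rows = _enrichment_rows(config, bins, truth, rt_res, breaks)
            enr = pd.DataFrame(rows)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        else:
            log.info("enrichment skipped (needs feature tracks and an RT profile)")

    files = sorted(str(p.name) for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    report["outputs"] = {
        name: hashlib.sha256((out / name).read_bytes()).hexdigest() for name in files
    }
    report["n_break_sites"] = int(len(breaks))
    report["aneuploidy_fraction"] = float(karyo.aneuploidy_fraction)
    if rt_res is not None:
        report["n_informative_s_cells"] = int(len(rt_res.binary))
        report["class_counts"] = rt_res.aggregate.class_counts()
    with open(out / "manifest.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _enrichment_rows(config, bins, truth, rt_res, breaks) -> list:
    """Early-vs-late feature comparisons plus break-site-vs-random tests."""
    gene_density = bin_track(truth.genes, bins, mode="count").astype(float)
    origin_density = bin_track(truth.origins, bins, mode="count").astype(float)
    classes = rt_res.aggregate.classes
    unmasked = bins.unmasked
    early = (classes == "early") & unmasked
    late = (classes == "late") & unmasked
    lad_track = truth.lad_track()

    rows = []
    feature_values = {
        "gene_density": gene_density,
        "origin_density": origin_density,
        "compartment": truth.compartment,
    }
    if bins.gc is not None:
        feature_values["gc"] = bins.gc
    for name, vals in feature_values.items():
        if early.sum() and late.sum():
            res = enrichment_test(vals[early], vals[late], statistic_name=f"{name}_early_vs_late")
            rows.append(_row(res, config.seed))

    # late-region lamina association vs random expectation
    late_sites = _bins_to_track(bins, late)
    if len(late_sites):
        oe = lamina_oe(late_sites, lad_track, bins)
        rows.append(
            {
                "statistic": "lamina_oe_late_bins", "observed": oe, "oe_ratio": oe,
                "U": np.nan, "p_two_sided": np.nan,
                "n_sites": len(late_sites), "n_null": 0, "seed": config.seed,
            }
        )

    if len(breaks):
        site_df = pd.DataFrame(
            {
                "chrom": breaks["chrom"],
                "start": breaks["position"],
                "end": breaks["position"] + 1,
            }
        )
        sites = IntervalTrack(site_df)
        n_null = max(config.n_null, len(sites))
        null_lengths = list(sites.lengths) * int(np.ceil(n_null / len(sites)))
        null = sample_random_regions(null_lengths[:n_null], bins, seed=config.seed + 17)
        for name, vals in {
            "gene_density": gene_density,
            "origin_density": origin_density,
            "replication_percentage": rt_res.aggregate.replication_percentage,
            "compartment": truth.compartment,
        }.items():
            res = enrichment_test(
                value_at_sites(sites, vals, bins, window_bins=1),
                value_at_sites(null.track, vals, bins, window_bins=1),
                statistic_name=f"{name}_breaks_vs_random",
            )
            rows.append(_row(res, config.seed))
        oe = lamina_oe(sites, lad_track, bins)
        rows.append(
            {
                "statistic": "lamina_oe_breaks", "observed": oe, "oe_ratio": oe,
                "U": np.nan, "p_two_sided": np.nan,
                "n_sites": len(sites), "n_null": len(null), "seed": config.seed,
            }
        )
    return rows


def _row(res, seed) -> dict:
    d = res.to_frame().iloc[0].to_dict()
    d["seed"] = seed
    return d


def _bins_to_track(bins, selector) -> IntervalTrack:
    rows = [
        (bins.chrom_names[bins.chrom_index[i]], int(bins.starts[i]), int(bins.ends[i]))
        for i in np.flatnonzero(selector)
    ]
    return IntervalTrack(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def _bins_from_columns(columns, bin_size):
    """Rebuild GenomeBins from 'chrom:start-end' count-table headers."""
    chrom_lengths: dict = {}
    for col in columns:
        chrom, rng = col.split(":")
        _, end = rng.split("-")
        chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), int(end))
    return partition_genome(chrom_lengths, bin_size)


def default_genome_gc(bins, seed):
    """Attach the synthetic GC field to an arbitrary binning."""
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)
    gc = np.empty(bins.n_bins)
    for chrom in bins.chrom_names:
        sl = bins.chrom_slice(chrom)
        z = gaussian_filter1d(rng.standard_normal(sl.stop - sl.start), 30, mode="nearest")
        z = (z - z.min()) / max(z.max() - z.min(), 1e-12)
        gc[sl] = 0.35 + 0.25 * z
    return bins.with_gc(gc)
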