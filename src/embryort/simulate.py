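"""Synthetic single-cell replication-timing data with known truth.

Emulates shallow whole-genome-amplified single-cell sequencing of early
embryo blastomeres: G1 cells with an even (1x-equivalent) copy profile
and S cells in which bins scheduled earlier than the cell's S-phase
fraction carry a doubled (2x) copy signal. Feature tracks (LADs, A/B
compartment eigenvector, replication origins, genes, GC) are generated
coupled to the replication-timing program so that downstream enrichment
statistics have a known expected direction. Whole-chromosome and
segmental copy-number events can be injected into individual cells.

Every generator is deterministic given its seed, and every dataset
carries enough truth (per-cell phase, S-fraction, binary states,
injected events) to score each downstream stage.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import InvalidArgumentError
from .genome import GenomeBins, IntervalTrack, partition_genome

__all__ = [
    "RTTruth",
    "CellTruth",
    "SimulatedCells",
    "default_genome",
    "make_rt_truth",
    "simulate_cells",
    "inject_cn_event",
]

# Desk-scale default genome: 2 chromosomes x 100 Mb at 100 kb bins
# (2,000 bins) — large enough for stable correlations, small enough to
# simulate in seconds.
DEFAULT_CHROM_LENGTHS = {"chr1": 100_000_000, "chr2": 100_000_000}
DEFAULT_BIN_SIZE = 100_000


def default_genome(bin_size: int = DEFAULT_BIN_SIZE, seed: int = 0) -> GenomeBins:
    """Desk-scale genome with a smooth synthetic GC track in [0.35, 0.60]."""
    bins = partition_genome(DEFAULT_CHROM_LENGTHS, bin_size)
    rng = np.random.default_rng(seed)
    gc = np.empty(bins.n_bins)
    for chrom in bins.chrom_names:
        sl = bins.chrom_slice(chrom)
        z = gaussian_filter1d(rng.standard_normal(sl.stop - sl.start), 30, mode="nearest")
        z = (z - z.min()) / max(z.max() - z.min(), 1e-12)
        gc[sl] = 0.35 + 0.25 * z
    return bins.with_gc(gc)


@dataclass
class RTTruth:
    """Ground-truth replication-timing program and coupled feature tracks.

    ``t`` is the scheduled replication time fraction per bin (0 =
    earliest, 1 = latest). With coupling strength kappa > 0, late bins
    are preferentially lamina-associated (corr(t, lad) > 0), in the B
    compartment (corr(t, compartment) < 0), and origin- and gene-poor.
    """

    bins: GenomeBins
    t: np.ndarray
    lad: np.ndarray  # per-bin boolean
    compartment: np.ndarray  # per-bin signed eigenvector-like score
    origins: IntervalTrack
    genes: IntervalTrack
    kappa: float
    seed: int

    def lad_track(self) -> IntervalTrack:
        """Merge consecutive LAD bins into an interval track."""
        rows = []
        b = self.bins
        for chrom in b.chrom_names:
            sl = b.chrom_slice(chrom)
            flags = self.lad[sl]
            i = 0
            n = sl.stop - sl.start
            while i < n:
                if flags[i]:
                    j = i
                    while j + 1 < n and flags[j + 1]:
                        j += 1
                    rows.append((chrom, int(b.starts[sl.start + i]), int(b.ends[sl.start + j])))
                    i = j + 1
                else:
                    i += 1
        return IntervalTrack(pd.DataFrame(rows, columns=["chrom", "start", "end"]), is_sorted=True)

    def expected_fraction(self, f_values: np.ndarray) -> np.ndarray:
        """Truth-implied expected per-bin replicated fraction E[1{t <= f}]
        over a cohort of S cells with the given S-phase fractions."""
        f = np.asarray(f_values, dtype=float)
        return (self.t[None, :] <= f[:, None]).mean(axis=0)


@dataclass
class CellTruth:
    cell_id: str
    phase: str  # "G1" | "S"
    s_fraction: float  # 0 for G1
    states: np.ndarray  # per-bin binary replication state (post flip noise)
    events: list = field(default_factory=list)  # (chrom, start, end, delta_cn)


@dataclass
class SimulatedCells:
    """Cells x bins count matrix plus full generating truth."""

    bins: GenomeBins
    truth: RTTruth
    counts: np.ndarray  # (n_cells, n_bins) non-negative ints
    cells: list  # list[CellTruth], row order matches counts
    seed: int

    @property
    def cell_ids(self) -> list:
        return [c.cell_id for c in self.cells]

    def counts_frame(self) -> pd.DataFrame:
        cols = [f"{c}:{s}-{e}" for c, s, e in self.bins.iter_bins()]
        return pd.DataFrame(self.counts, index=self.cell_ids, columns=cols)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "phase": [c.phase for c in self.cells],
                "s_fraction": [c.s_fraction for c in self.cells],
                "n_events": [len(c.events) for c in self.cells],
            }
        )

    def write_tsv(self, counts_path, truth_path=None) -> None:
        self.counts_frame().to_csv(counts_path, sep="\t", index_label="cell_id")
        if truth_path is not None:
            self.truth_frame().to_csv(truth_path, sep="\t", index=False)


def _smooth_field(rng, n: int, corr_len: float) -> np.ndarray:
    return gaussian_filter1d(rng.standard_normal(n), corr_len, mode="nearest")


def _rank_to_unit(x: np.ndarray) -> np.ndarray:
    """Map through the empirical CDF onto [0, 1]."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(x))
    return ranks / max(len(x) - 1, 1)


def make_rt_truth(
    bins: GenomeBins,
    correlation_length_bins: int = 20,
    coupling: float = 2.0,
    seed: int = 0,
    origins_per_mb: float = 1.0,
    genes_per_mb: float = 1.5,
) -> RTTruth:
    """Generate a smooth replication-timing program with coupled tracks.

    ``t`` is a per-chromosome Gaussian-smoothed noise field (smoothing
    scale ``correlation_length_bins``) mapped through its empirical CDF
    onto [0, 1]. LAD membership is Bernoulli with logistic probability
    in ``coupling * (t - 0.5)``; the compartment score is
    ``-coupling * (t - 0.5)`` plus smooth unit noise; origins and genes
    are placed with intensity proportional to ``exp(-coupling * t)``
    (early bins are origin- and gene-rich). ``coupling = 0`` decouples
    every track from ``t``.
    """
    if correlation_length_bins < 1:
        raise InvalidArgumentError("correlation_length_bins must be >= 1")
    if coupling < 0:
        raise InvalidArgumentError(f"coupling must be >= 0, got {coupling}")
    rng = np.random.default_rng(seed)
    n = bins.n_bins
    raw = np.empty(n)
    for chrom in bins.chrom_names:
        sl = bins.chrom_slice(chrom)
        raw[sl] = _smooth_field(rng, sl.stop - sl.start, correlation_length_bins)
    t = _rank_to_unit(raw)

    # LADs are contiguous Mb-scale domains, not independent per-bin
    # draws: threshold a smooth latent field tilted by the coupling, so
    # late bins are lamina-associated with probability increasing in
    # coupling * (t - 0.5) while domains stay blocky like real LADs
    lad_latent = np.empty(n)
    for chrom in bins.chrom_names:
        sl = bins.chrom_slice(chrom)
        lad_latent[sl] = _smooth_field(rng, sl.stop - sl.start, correlation_length_bins)
    lad_latent /= max(lad_latent.std(), 1e-12)
    lad = 0.5 * lad_latent + coupling * (t - 0.5) > 0

    comp_noise = np.empty(n)
    for chrom in bins.chrom_names:
        sl = bins.chrom_slice(chrom)
        comp_noise[sl] = _smooth_field(rng, sl.stop - sl.start, correlation_length_bins)
    comp_noise /= max(comp_noise.std(), 1e-12)
    compartment = -coupling * (t - 0.5) + comp_noise

    intensity = np.exp(-coupling * t)
    origins = _point_process(rng, bins, intensity, origins_per_mb, point=True)
    genes = _point_process(rng, bins, intensity, genes_per_mb, point=False)
    return RTTruth(
        bins=bins, t=t, lad=lad, compartment=compartment,
        origins=origins, genes=genes, kappa=float(coupling), seed=int(seed),
    )


def _point_process(rng, bins, intensity, per_mb, point):
    """Inhomogeneous placement of origins (points) or genes (intervals)."""
    genome_mb = sum(bins.chrom_lengths.values()) / 1e6
    target = max(1, int(round(per_mb * genome_mb)))
    lam = intensity / intensity.sum() * target
    counts = rng.poisson(lam)
    rows = []
    k = 0
    for i in np.flatnonzero(counts):
        chrom = bins.chrom_names[bins.chrom_index[i]]
        for _ in range(int(counts[i])):
            pos = int(rng.integers(bins.starts[i], bins.ends[i]))
            if point:
                rows.append((chrom, pos, pos + 1, f"ori{k}"))
            else:
                # gene lengths ~ lognormal, median 30 kb; heavy right tail
                # yields occasional >500 kb genes for long-gene analyses
                length = int(np.exp(rng.normal(np.log(30_000), 1.0)))
                end = min(pos + max(length, 1000), bins.chrom_lengths[chrom])
                if end > pos:
                    rows.append((chrom, pos, end, f"g{k}"))
            k += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return IntervalTrack(df).sort()


def simulate_cells(
    truth: RTTruth,
    n_g1: int = 30,
    n_s: int = 150,
    mean_reads_per_cell: int = 1_000_000,
    nb_dispersion: float = 10.0,
    amp_noise_sd: float = 0.1,
    gc_coeff: float = 0.3,
    flip_rate: float = 0.0,
    f_range: tuple = (0.05, 0.95),
    seed: int = 0,
) -> SimulatedCells:
    """Simulate binned read counts for G1 and S cells.

    For S cell ``c`` the S-phase fraction ``f_c ~ Uniform(f_range)``;
    bin ``b`` is replicated iff ``t_b <= f_c``, then flipped
    independently with probability ``flip_rate`` (models binarisation-
    scale noise). The expected count is proportional to
    ``(1 + state) * exp(N(0, amp_noise_sd)) * exp(gc_coeff * (gc - mean gc))``
    rescaled to ``mean_reads_per_cell`` total, and counts are drawn
    negative-binomially with variance ``mu + mu^2 / nb_dispersion``
    (``nb_dispersion=None`` or inf gives Poisson). G1 cells are
    unreplicated everywhere.
    """
    if n_g1 + n_s < 1:
        raise InvalidArgumentError("need at least one cell")
    if not (0.0 <= flip_rate < 0.5):
        raise InvalidArgumentError(f"flip_rate must be in [0, 0.5), got {flip_rate}")
    f_min, f_max = f_range
    if not (0.0 < f_min < f_max < 1.0):
        raise InvalidArgumentError(f"need 0 < f_min < f_max < 1, got {f_range}")
    bins = truth.bins
    rng = np.random.default_rng(seed)
    n_bins = bins.n_bins
    gc = bins.gc if bins.gc is not None else np.full(n_bins, 0.5)
    gc_term = np.exp(gc_coeff * (gc - np.nanmean(gc)))

    cells: list = []
    counts = np.zeros((n_g1 + n_s, n_bins), dtype=np.int64)
    for row in range(n_g1 + n_s):
        if row < n_g1:
            cell_id, phase, f = f"G1_{row:03d}", "G1", 0.0
            states = np.zeros(n_bins, dtype=np.int8)
        else:
            cell_id, phase = f"S_{row - n_g1:03d}", "S"
            f = float(rng.uniform(f_min, f_max))
            states = (truth.t <= f).astype(np.int8)
            if flip_rate > 0:
                flips = rng.random(n_bins) < flip_rate
                states = np.where(flips, 1 - states, states).astype(np.int8)
        mu = (1.0 + states).astype(float)
        if amp_noise_sd > 0:
            mu = mu * np.exp(rng.normal(0.0, amp_noise_sd, n_bins))
        mu = mu * gc_term
        mu *= mean_reads_per_cell / mu.sum()
        counts[row] = _draw_counts(rng, mu, nb_dispersion)
        cells.append(CellTruth(cell_id=cell_id, phase=phase, s_fraction=f, states=states))
    return SimulatedCells(bins=bins, truth=truth, counts=counts, cells=cells, seed=int(seed))


def _draw_counts(rng, mu, dispersion):
    if dispersion is None or not np.isfinite(dispersion):
        return rng.poisson(mu)
    if dispersion <= 0:
        raise InvalidArgumentError(f"nb_dispersion must be positive, got {dispersion}")
    # NB with mean mu, var mu + mu^2/r: gamma-Poisson mixture
    shape = float(dispersion)
    lam = rng.gamma(shape, mu / shape)
    return rng.poisson(lam)


def inject_cn_event(
    cells: SimulatedCells,
    cell_id: str,
    region,
    delta_cn: int,
    baseline_cn: int = 2,
    seed: int = 0,
) -> SimulatedCells:
    """Inject a copy-number event into one cell; returns a new dataset.

    ``region`` is a chromosome name (whole-chromosome event) or a
    (chrom, start, end) triple. Counts of bins overlapping the region
    are multiplied by ``(baseline_cn + delta_cn) / baseline_cn`` and
    re-rounded stochastically so expectations are exact. The event is
    recorded in the cell's truth.
    """
    if delta_cn == 0:
        raise InvalidArgumentError("delta_cn must be nonzero")
    if baseline_cn + delta_cn < 0:
        raise InvalidArgumentError(
            f"baseline_cn + delta_cn must be >= 0, got {baseline_cn + delta_cn}"
        )
    bins = cells.bins
    if isinstance(region, str):
        if region not in bins.chrom_names:
            raise InvalidArgumentError(f"unknown chromosome {region!r}")
        region = (region, 0, bins.chrom_lengths[region])
    chrom, start, end = region
    if chrom not in bins.chrom_names:
        raise InvalidArgumentError(f"unknown chromosome {chrom!r}")
    if not (0 <= start < end <= bins.chrom_lengths[chrom]):
        raise InvalidArgumentError(f"region {region} outside chromosome bounds")
    try:
        row = cells.cell_ids.index(cell_id)
    except ValueError:
        raise InvalidArgumentError(f"unknown cell_id {cell_id!r}") from None

    sl = bins.chrom_slice(chrom)
    in_region = (bins.starts[sl] < end) & (bins.ends[sl] > start)
    idx = np.flatnonzero(in_region) + sl.start

    out = copy.deepcopy(cells)
    mult = (baseline_cn + delta_cn) / baseline_cn
    rng = np.random.default_rng(seed)
    scaled = out.counts[row, idx] * mult
    floor = np.floor(scaled)
    out.counts[row, idx] = (floor + (rng.random(len(idx)) < (scaled - floor))).astype(np.int64)
    out.cells[row].events.append((chrom, int(start), int(end), int(delta_cn)))
    return out
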