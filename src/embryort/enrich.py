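"""Feature enrichment at genomic sites versus random-region nulls.

Break sites and early/late replicating regions are compared against
length-matched random regions: per-site feature values (gene density,
origin density, GC, replication percentage), lamina-association
observed/expected (OE) ratios, A/B compartment assignment, and the
rank (Mann-Whitney) and one-way ANOVA tests used to compare groups.

Random regions are sampled uniformly over all positions where an
interval of the requested length fits entirely inside a maximal
unmasked stretch of the genome, so the null never touches masked
territory and is exactly length-matched to the query set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    InvalidArgumentError,
    SamplingFailureError,
    UndefinedStatisticError,
)
from .genome import GenomeBins, IntervalTrack

__all__ = [
    "RandomRegionSet",
    "EnrichmentResult",
    "sample_random_regions",
    "value_at_sites",
    "lamina_oe",
    "compartment_at_sites",
    "derive_region_sets",
    "mann_whitney",
    "one_way_anova",
    "enrichment_test",
]

#: Default number of random sites in a break-site null set.
DEFAULT_NULL_SITES = 360


@dataclass
class RandomRegionSet:
    """Random intervals matched in count and lengths to a query set."""

    track: IntervalTrack
    seed: int

    def __len__(self) -> int:
        return len(self.track)


def _unmasked_stretches(bins: GenomeBins) -> list:
    """Maximal runs of unmasked bins as (chrom, start, end) bp intervals."""
    out = []
    for chrom in bins.chrom_names:
        sl = bins.chrom_slice(chrom)
        ok = bins.unmasked[sl]
        i = 0
        n = sl.stop - sl.start
        while i < n:
            if ok[i]:
                j = i
                while j + 1 < n and ok[j + 1]:
                    j += 1
                out.append(
                    (chrom, int(bins.starts[sl.start + i]), int(bins.ends[sl.start + j]))
                )
                i = j + 1
            else:
                i += 1
    return out


def sample_random_regions(
    query_lengths,
    bins: GenomeBins,
    n_sets: int = 1,
    seed: int = 0,
):
    """Length-matched random region sets avoiding masked territory.

    For each query length a start position is drawn uniformly over all
    positions where the full interval fits inside one maximal unmasked
    stretch (stretch chosen with probability proportional to its number
    of valid starts). Deterministic given ``seed``. Returns one
    ``RandomRegionSet`` (n_sets=1) or a list of them.
    """
    lengths = [int(v) for v in query_lengths]
    if any(v <= 0 for v in lengths):
        raise InvalidArgumentError("query lengths must be positive")
    stretches = _unmasked_stretches(bins)
    if not stretches:
        raise SamplingFailureError("genome is fully masked")
    s_len = np.array([e - s for _, s, e in stretches], dtype=np.int64)
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        rows = []
        for L in lengths:
            slots = s_len - L + 1
            valid = slots > 0
            if not valid.any():
                raise SamplingFailureError(
                    f"no unmasked stretch can hold an interval of {L} bp"
                )
            p = np.where(valid, slots, 0).astype(float)
            k = rng.choice(len(stretches), p=p / p.sum())
            chrom, s0, _ = stretches[k]
            start = s0 + int(rng.integers(0, slots[k]))
            rows.append((chrom, start, start + L))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        sets.append(RandomRegionSet(track=IntervalTrack(df), seed=int(seed)))
    return sets[0] if n_sets == 1 else sets


def value_at_sites(
    sites: IntervalTrack,
    values: np.ndarray,
    bins: GenomeBins,
    window_bins: int = 0,
) -> np.ndarray:
    """Mean per-bin value over the bins each site overlaps.

    The site is extended by ``window_bins`` bins on each side; masked
    bins are ignored, and a site whose bins are all masked gets NaN.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (bins.n_bins,):
        raise InvalidArgumentError("values must be per-bin")
    out = np.full(len(sites), np.nan)
    for i, row in enumerate(sites.df.itertuples(index=False)):
        sl = bins.chrom_slice(row.chrom)
        n_chrom = sl.stop - sl.start
        first = max(int(row.start) // bins.bin_size - window_bins, 0)
        last = min((int(row.end) - 1) // bins.bin_size + window_bins, n_chrom - 1)
        idx = np.arange(first, last + 1) + sl.start
        idx = idx[bins.unmasked[idx] & np.isfinite(v[idx])]
        if idx.size:
            out[i] = v[idx].mean()
    return out


def lamina_oe(
    sites: IntervalTrack,
    lad_track: IntervalTrack,
    bins: GenomeBins,
    min_overlap_fraction: float = 0.0,
) -> float:
    """Lamina-association observed/expected ratio for a site set.

    observed = fraction of sites overlapping a LAD (any bp by default;
    ``min_overlap_fraction`` requires that fraction of the site to be
    covered); expected = LAD bp coverage fraction of the unmasked
    genome. OE > 1 means more lamina association than random.
    """
    if len(sites) == 0:
        raise InvalidArgumentError("empty site set")
    lads = lad_track.clipped(bins).merged()
    unmasked_bp = int(bins.bin_lengths[bins.unmasked].sum())
    if unmasked_bp == 0:
        raise UndefinedStatisticError("unmasked genome length is zero")
    # LAD bp restricted to unmasked bins: total LAD length minus the
    # part falling in masked bins (few masked bins, so iterate those)
    lad_bp = 0
    by_chrom = {c: sub for c, sub in lads.df.groupby("chrom", sort=False)}
    for chrom, sub in by_chrom.items():
        sl = bins.chrom_slice(chrom)
        masked_idx = np.flatnonzero(bins.mask[sl]) + sl.start
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        lad_bp += int((ends - starts).sum())
        for gi in masked_idx:
            ov = np.minimum(ends, bins.ends[gi]) - np.maximum(starts, bins.starts[gi])
            lad_bp -= int(ov[ov > 0].sum())
    expected = lad_bp / unmasked_bp
    if expected == 0:
        raise UndefinedStatisticError("LAD coverage of unmasked genome is zero")
    observed = np.mean(
        [
            _site_overlaps(row, by_chrom, min_overlap_fraction)
            for row in sites.df.itertuples(index=False)
        ]
    )
    return float(observed / expected)


def _site_overlaps(row, lads_by_chrom, min_frac) -> bool:
    sub = lads_by_chrom.get(row.chrom)
    if sub is None:
        return False
    s, e = int(row.start), int(row.end)
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    ov = np.minimum(ends, e) - np.maximum(starts, s)
    total = int(ov[ov > 0].sum())
    if min_frac <= 0:
        return total > 0
    return total >= min_frac * (e - s)


def compartment_at_sites(
    sites: IntervalTrack,
    eigenvector: np.ndarray,
    bins: GenomeBins,
) -> pd.DataFrame:
    """Per-site mean A/B compartment eigenvector and sign label.

    Positive mean -> "A", negative -> "B", exactly zero or undefined ->
    "unassigned" (the sign convention is silent at zero).
    """
    vals = value_at_sites(sites, eigenvector, bins)
    labels = np.where(
        np.isnan(vals), "unassigned", np.where(vals > 0, "A", np.where(vals < 0, "B", "unassigned"))
    )
    return pd.DataFrame({"value": vals, "label": labels})


def derive_region_sets(
    genes: IntervalTrack,
    min_gene_bp: int = 500_000,
    min_intergenic_bp: int = 1_000_000,
    chrom_lengths=None,
):
    """Long-gene and long-intergenic region sets.

    Long genes: merged gene intervals strictly longer than
    ``min_gene_bp`` (default 500 kb). Intergenic: gaps between merged
    gene intervals, including chromosome ends when ``chrom_lengths``
    is given, strictly longer than ``min_intergenic_bp`` (default 1 Mb).
    """
    import warnings as _warnings

    if len(genes) == 0:
        _warnings.warn("empty gene track; region sets are empty", stacklevel=2)
        empty = IntervalTrack(pd.DataFrame(columns=["chrom", "start", "end"]))
        return empty, IntervalTrack(empty.df.copy())
    merged = genes.merged()
    long_genes = merged.df[(merged.df["end"] - merged.df["start"]) > min_gene_bp]
    gaps = []
    for chrom, sub in merged.df.groupby("chrom", sort=True):
        prev = 0
        for s, e in zip(sub["start"], sub["end"]):
            if s - prev > min_intergenic_bp:
                gaps.append((chrom, prev, s))
            prev = max(prev, e)
        if chrom_lengths is not None and chrom in chrom_lengths:
            if chrom_lengths[chrom] - prev > min_intergenic_bp:
                gaps.append((chrom, prev, chrom_lengths[chrom]))
    long_gene_track = IntervalTrack(long_genes.reset_index(drop=True), is_sorted=True)
    intergenic = IntervalTrack(
        pd.DataFrame(gaps, columns=["chrom", "start", "end"]), is_sorted=True
    )
    # leading gap starting at 0 without chrom_lengths context is kept only
    # if it lies strictly between genes; drop zero-length artefacts
    intergenic = IntervalTrack(
        intergenic.df[intergenic.df["start"] < intergenic.df["end"]].reset_index(drop=True),
        is_sorted=True,
    )
    return long_gene_track, intergenic


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def mann_whitney(a, b, alternative: str = "two-sided") -> tuple:
    """Mann-Whitney U test; U reported for group ``a``.

    Uses the exact permutation distribution when both groups have at
    most 8 observations and no value is shared between or within
    groups; otherwise the normal approximation with tie and continuity
    correction.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidArgumentError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size <= 8 and b.size <= 8 and no_ties:
        res = sps.mannwhitneyu(a, b, alternative=alternative, method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative=alternative, method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups) -> tuple:
    """Classical one-way ANOVA F and p over >= 2 groups."""
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InvalidArgumentError("need >= 2 groups")
    if any(g.size < 2 for g in arrays):
        raise InvalidArgumentError("each group needs >= 2 observations")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    if ss_within == 0 and ss_between == 0:
        raise UndefinedStatisticError("zero variance within and between groups")
    df_b = len(arrays) - 1
    df_w = sum(g.size for g in arrays) - len(arrays)
    if df_w < 1:
        raise InvalidArgumentError("total error degrees of freedom < 1")
    if ss_within == 0:
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


@dataclass
class EnrichmentResult:
    """Site-vs-null comparison: values, OE ratio, rank-test statistics."""

    statistic_name: str
    site_values: np.ndarray
    null_values: np.ndarray
    observed_stat: float
    u_statistic: float
    p_two_sided: float
    n_sites: int
    n_null: int
    oe_ratio: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "statistic": self.statistic_name,
                    "observed": self.observed_stat,
                    "oe_ratio": self.oe_ratio if self.oe_ratio is not None else np.nan,
                    "U": self.u_statistic,
                    "p_two_sided": self.p_two_sided,
                    "n_sites": self.n_sites,
                    "n_null": self.n_null,
                }
            ]
        )

    def summary(self) -> str:
        oe = f", OE={self.oe_ratio:.3f}" if self.oe_ratio is not None else ""
        return (
            f"{self.statistic_name}: sites median {np.nanmedian(self.site_values):.4g} "
            f"vs null {np.nanmedian(self.null_values):.4g}{oe} "
            f"(U={self.u_statistic:.1f}, p={self.p_two_sided:.3g}, "
            f"n={self.n_sites}/{self.n_null})"
        )


def enrichment_test(
    site_values,
    null_values,
    statistic_name: str = "value",
    oe_ratio: float | None = None,
) -> EnrichmentResult:
    """Two-sided Mann-Whitney comparison of site vs null values."""
    sv = np.asarray(site_values, dtype=float)
    nv = np.asarray(null_values, dtype=float)
    sv_f, nv_f = sv[np.isfinite(sv)], nv[np.isfinite(nv)]
    u, p = mann_whitney(sv_f, nv_f)
    return EnrichmentResult(
        statistic_name=statistic_name,
        site_values=sv,
        null_values=nv,
        observed_stat=float(np.median(sv_f)) if sv_f.size else float("nan"),
        u_statistic=u,
        p_two_sided=p,
        n_sites=int(sv_f.size),
        n_null=int(nv_f.size),
        oe_ratio=oe_ratio,
    )
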