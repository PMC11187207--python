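"""Genome binning and interval-track utilities.

The coordinate backbone of the whole pipeline: fixed-size tilings of a
genome (``GenomeBins``), lightweight interval tracks (``IntervalTrack``,
backed by a pandas DataFrame), and per-bin summarisation of tracks
(counts, coverage fractions, coverage-weighted mean scores).

All coordinates are 0-based half-open (BED convention) everywhere
internally; 1-based inputs must be converted at the boundary (see
``shift_to_zero_based``). Chromosome name matching is exact string match;
``rename_chroms`` applies a user-supplied alias table for the
"chr1" vs "1" dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, ParseError

__all__ = [
    "GenomeBins",
    "IntervalTrack",
    "partition_genome",
    "read_chrom_sizes",
    "read_interval_track",
    "bin_track",
    "write_bedgraph",
    "write_bed",
    "rename_chroms",
]


@dataclass(frozen=True)
class GenomeBins:
    """Contiguous fixed-size tiling of a genome.

    Bins tile each chromosome without gaps or overlap; every bin has
    length ``bin_size`` except possibly the last bin of each chromosome.
    ``mask`` flags bins excluded from analysis (True = excluded); by
    default the short terminal bin of each chromosome is masked because
    its read-count exposure differs from full bins.

    Attributes
    ----------
    chrom_names : tuple of str
        Chromosome names in input order.
    chrom_lengths : mapping str -> int
        Chromosome lengths in bp.
    bin_size : int
        Nominal bin width in bp.
    chrom_index : ndarray of int
        Per-bin index into ``chrom_names``.
    starts, ends : ndarray of int
        Per-bin 0-based half-open coordinates.
    gc : ndarray of float or None
        Per-bin GC fraction in [0, 1]; NaN where unknown.
    mask : ndarray of bool
        True = bin excluded from analysis.
    """

    chrom_names: tuple
    chrom_lengths: dict
    bin_size: int
    chrom_index: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    gc: np.ndarray | None = None
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.mask is None:
            object.__setattr__(self, "mask", np.zeros(len(self.starts), dtype=bool))
        if self.gc is not None:
            g = np.asarray(self.gc, dtype=float)
            ok = np.isnan(g) | ((g >= 0.0) & (g <= 1.0))
            if not ok.all():
                raise InvalidArgumentError("gc fractions must lie in [0, 1]")
            object.__setattr__(self, "gc", g)

    # -- basic geometry -------------------------------------------------

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    @property
    def bin_lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def unmasked(self) -> np.ndarray:
        """Boolean selector of analysable bins."""
        return ~self.mask

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous slice of bin indices belonging to one chromosome."""
        try:
            ci = self.chrom_names.index(chrom)
        except ValueError:
            raise InvalidArgumentError(f"unknown chromosome {chrom!r}") from None
        idx = np.flatnonzero(self.chrom_index == ci)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chrom_of(self, bin_index: int) -> str:
        return self.chrom_names[self.chrom_index[bin_index]]

    def iter_bins(self) -> Iterable[tuple]:
        names = self.chrom_names
        for ci, s, e in zip(self.chrom_index, self.starts, self.ends):
            yield names[ci], int(s), int(e)

    def with_gc(self, gc: np.ndarray) -> "GenomeBins":
        return replace(self, gc=np.asarray(gc, dtype=float))

    def with_mask(self, mask: np.ndarray) -> "GenomeBins":
        return replace(self, mask=np.asarray(mask, dtype=bool))

    def bin_at(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing position ``pos``."""
        sl = self.chrom_slice(chrom)
        length = self.chrom_lengths[chrom]
        if not 0 <= pos < length:
            raise InvalidArgumentError(f"position {pos} outside {chrom} (length {length})")
        return sl.start + min(pos // self.bin_size, sl.stop - sl.start - 1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [self.chrom_names[i] for i in self.chrom_index],
                "start": self.starts,
                "end": self.ends,
                "mask": self.mask,
            }
        )
        if self.gc is not None:
            df["gc"] = self.gc
        return df


def partition_genome(
    chrom_lengths: Mapping[str, int],
    bin_size: int,
    mask_partial: bool = True,
) -> GenomeBins:
    """Tile each chromosome into ``bin_size`` bins (last bin may be short).

    Per-chromosome bin count is ``ceil(length / bin_size)``. With
    ``mask_partial`` (default) short terminal bins are flagged in
    ``mask`` — they still exist in the tiling but are excluded from
    analysis because their exposure differs from full bins.
    """
    if int(bin_size) <= 0:
        raise InvalidArgumentError(f"bin_size must be positive, got {bin_size}")
    bin_size = int(bin_size)
    names = tuple(chrom_lengths)
    if not names:
        raise InvalidArgumentError("chrom_lengths is empty")
    chrom_index, starts, ends = [], [], []
    for ci, name in enumerate(names):
        length = int(chrom_lengths[name])
        if length <= 0:
            raise InvalidArgumentError(f"chromosome {name!r} has non-positive length {length}")
        edges = np.arange(0, length + bin_size, bin_size)
        edges[-1] = min(edges[-1], length)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        starts.append(edges[:-1])
        ends.append(edges[1:])
        chrom_index.append(np.full(len(edges) - 1, ci, dtype=np.int64))
    starts = np.concatenate(starts)
    ends = np.concatenate(ends)
    chrom_index = np.concatenate(chrom_index)
    mask = np.zeros(len(starts), dtype=bool)
    if mask_partial:
        mask = (ends - starts) != bin_size
    return GenomeBins(
        chrom_names=names,
        chrom_lengths={k: int(v) for k, v in chrom_lengths.items()},
        bin_size=bin_size,
        chrom_index=chrom_index,
        starts=starts,
        ends=ends,
        mask=mask,
    )


# ---------------------------------------------------------------------------
# Interval tracks
# ---------------------------------------------------------------------------


@dataclass
class IntervalTrack:
    """A set of genomic intervals with optional per-interval score/name.

    Backed by a DataFrame with columns chrom, start, end and optionally
    score and name. Coordinates are 0-based half-open.
    """

    df: pd.DataFrame
    is_sorted: bool = False

    def __post_init__(self):
        required = {"chrom", "start", "end"}
        if not required.issubset(self.df.columns):
            raise InvalidArgumentError(f"track requires columns {sorted(required)}")
        if len(self.df) and not (self.df["start"] < self.df["end"]).all():
            raise InvalidArgumentError("intervals must satisfy start < end")

    @classmethod
    def from_records(cls, records: Sequence[tuple], scores=None) -> "IntervalTrack":
        df = pd.DataFrame(records, columns=["chrom", "start", "end"][: len(records[0]) if records else 3])
        if scores is not None:
            df["score"] = scores
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_score(self) -> bool:
        return "score" in self.df.columns

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def sort(self) -> "IntervalTrack":
        df = self.df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        return IntervalTrack(df, is_sorted=True)

    def subset(self, chrom: str) -> "IntervalTrack":
        return IntervalTrack(self.df[self.df["chrom"] == chrom].reset_index(drop=True), self.is_sorted)

    def merged(self) -> "IntervalTrack":
        """Union of intervals: overlapping/abutting intervals are fused."""
        out = []
        for chrom, sub in self.sort().df.groupby("chrom", sort=True):
            cur_s = cur_e = None
            for s, e in zip(sub["start"], sub["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    out.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                out.append((chrom, cur_s, cur_e))
        df = pd.DataFrame(out, columns=["chrom", "start", "end"])
        return IntervalTrack(df, is_sorted=True)

    def total_bp(self) -> int:
        return int(self.lengths.sum())

    def clipped(self, bins: GenomeBins) -> "IntervalTrack":
        """Clip intervals to chromosome bounds; drop unknown chromosomes."""
        df = self.df[self.df["chrom"].isin(bins.chrom_names)].copy()
        lengths = df["chrom"].map(bins.chrom_lengths)
        df["start"] = df["start"].clip(lower=0)
        df["end"] = np.minimum(df["end"], lengths)
        df = df[df["start"] < df["end"]].reset_index(drop=True)
        return IntervalTrack(df, self.is_sorted)


def shift_to_zero_based(track: IntervalTrack) -> IntervalTrack:
    """Convert a 1-based closed track to 0-based half-open in place."""
    df = track.df.copy()
    df["start"] = df["start"] - 1
    return IntervalTrack(df, track.is_sorted)


def rename_chroms(track: IntervalTrack, alias: Mapping[str, str]) -> IntervalTrack:
    """Apply an alias table (e.g. {"1": "chr1"}) to chromosome names."""
    df = track.df.copy()
    df["chrom"] = df["chrom"].map(lambda c: alias.get(c, c))
    return IntervalTrack(df, is_sorted=False)


# ---------------------------------------------------------------------------
# Text I/O — BED3/BED4, bedGraph, chrom.sizes
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def read_chrom_sizes(path) -> dict:
    """Two-column TSV (name, length) -> ordered dict of lengths."""
    sizes: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("expected 2 columns (name, length)", path, lineno)
            try:
                length = int(parts[1])
            except ValueError:
                raise ParseError(f"non-integer length {parts[1]!r}", path, lineno) from None
            if length <= 0:
                raise ParseError(f"non-positive length {length}", path, lineno)
            sizes[parts[0]] = length
    if not sizes:
        raise ParseError("no chromosomes found", path)
    return sizes


def read_interval_track(path, format: str | None = None) -> IntervalTrack:
    """Parse a BED (>= 3 columns) or bedGraph (exactly 4 columns) file.

    ``format`` is "bed" or "bedgraph"; inferred from the file extension
    when omitted. bedGraph column 4 is stored as ``score``; BED columns
    4 and 5, when present, as ``name`` and ``score``.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "bedgraph" if suffix in (".bedgraph", ".bg") else "bed"
    if format not in ("bed", "bedgraph"):
        raise InvalidArgumentError(f"unknown format {format!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            parts = line.split("\t")
            if format == "bedgraph" and len(parts) != 4:
                raise ParseError(f"bedGraph needs exactly 4 columns, got {len(parts)}", path, lineno)
            if len(parts) < 3:
                raise ParseError(f"need >= 3 columns, got {len(parts)}", path, lineno)
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError("non-numeric coordinates", path, lineno) from None
            if start < 0 or start >= end:
                raise ParseError(f"invalid interval [{start}, {end})", path, lineno)
            row = {"chrom": chrom, "start": start, "end": end}
            if format == "bedgraph":
                try:
                    row["score"] = float(parts[3])
                except ValueError:
                    raise ParseError(f"non-numeric score {parts[3]!r}", path, lineno) from None
            else:
                if len(parts) >= 4:
                    row["name"] = parts[3]
                if len(parts) >= 5:
                    try:
                        row["score"] = float(parts[4])
                    except ValueError:
                        raise ParseError(f"non-numeric score {parts[4]!r}", path, lineno) from None
            rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    df = df.dropna(axis=1, how="all")
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    return IntervalTrack(df)


def write_bed(track: IntervalTrack, path) -> None:
    """Write sorted BED; name and score columns included when present."""
    df = track.sort().df
    cols = ["chrom", "start", "end"]
    if "name" in df.columns:
        cols.append("name")
        if "score" in df.columns:
            cols.append("score")
    elif "score" in df.columns:
        df = df.assign(name=".")
        cols += ["name", "score"]
    with open(path, "w") as fh:
        for row in df[cols].itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_bedgraph(values, bins: GenomeBins, path) -> None:
    """Write one bedGraph record per unmasked bin with a finite value.

    ``values`` must be a full-length per-bin array (one entry per bin of
    ``bins``); masked bins and NaN entries are omitted from the output.
    Round-trips through ``read_interval_track`` + ``bin_track`` with
    mode="mean_score" to the written precision.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (bins.n_bins,):
        raise InvalidArgumentError(
            f"expected {bins.n_bins} per-bin values, got shape {values.shape}"
        )
    with open(path, "w") as fh:
        for i in range(bins.n_bins):
            if bins.mask[i] or not np.isfinite(values[i]):
                continue
            fh.write(
                f"{bins.chrom_names[bins.chrom_index[i]]}\t{bins.starts[i]}\t"
                f"{bins.ends[i]}\t{_fmt(values[i])}\n"
            )


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return format(float(v), ".6g")
    return str(v)


# ---------------------------------------------------------------------------
# Per-bin summarisation
# ---------------------------------------------------------------------------


def bin_track(track: IntervalTrack, bins: GenomeBins, mode: str = "count") -> np.ndarray:
    """Summarise an interval track per bin.

    mode="count"
        Number of intervals whose midpoint falls in the bin. The
        midpoint rule prevents double counting of features that span a
        bin boundary.
    mode="coverage_fraction"
        Overlapped bp / bin length, in [0, 1].
    mode="mean_score"
        Coverage-weighted mean score over overlapping intervals; NaN
        for bins with no overlap.

    Track chromosomes must be a subset of the binning's chromosomes.
    """
    if mode not in ("count", "coverage_fraction", "mean_score"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    if mode == "mean_score" and not track.has_score:
        raise InvalidArgumentError("mean_score requires a track with scores")
    extra = set(track.df["chrom"]) - set(bins.chrom_names)
    if extra:
        raise InvalidArgumentError(f"track chromosomes not in genome: {sorted(extra)}")

    n = bins.n_bins
    if mode == "count":
        out = np.zeros(n, dtype=np.int64)
    else:
        wsum = np.zeros(n)
        vsum = np.zeros(n)

    bs = bins.bin_size
    for chrom, sub in track.df.groupby("chrom", sort=False):
        sl = bins.chrom_slice(chrom)
        n_chrom = sl.stop - sl.start
        chrom_len = bins.chrom_lengths[chrom]
        starts = sub["start"].to_numpy().clip(0, chrom_len)
        ends = sub["end"].to_numpy().clip(0, chrom_len)
        if mode == "count":
            mids = (starts + ends) // 2
            idx = np.minimum(mids // bs, n_chrom - 1) + sl.start
            np.add.at(out, idx, 1)
            continue
        scores = sub["score"].to_numpy(dtype=float) if track.has_score else None
        for j in range(len(starts)):
            s, e = int(starts[j]), int(ends[j])
            if s >= e:
                continue
            first = min(s // bs, n_chrom - 1)
            last = min((e - 1) // bs, n_chrom - 1)
            for b in range(first, last + 1):
                gi = sl.start + b
                ov = min(e, bins.ends[gi]) - max(s, bins.starts[gi])
                if ov <= 0:
                    continue
                wsum[gi] += ov
                if scores is not None:
                    vsum[gi] += ov * scores[j]

    if mode == "count":
        return out
    if mode == "coverage_fraction":
        return wsum / bins.bin_lengths
    with np.errstate(invalid="ignore"):
        result = np.where(wsum > 0, vsum / np.where(wsum > 0, wsum, 1.0), np.nan)
    return result
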