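"""Single-cell replication-timing inference.

Each S-phase cell's corrected copy-ratio profile is bimodal: bins that
have replicated carry roughly twice the signal of bins that have not.
``binarize_cell`` splits the profile at the exact two-cluster 1-D SSE
optimum (2-means) and calls every bin replicated/unreplicated; cells
whose two cluster centers are closer than ``min_sep`` carry no usable
replication signal (very early or very late S) and are dropped.
Aggregating the binary states over cells yields the replication
percentage per bin — the fraction of S cells in which the bin has
replicated — from which early (> 50 %) and late (< 50 %) replicating
regions are defined.

The module follows the Model/Results pattern::

    model = ReplicationTimingModel(ratios, bins)
    res = model.fit()
    res.aggregate.replication_percentage
    res.summary()
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidArgumentError,
    UndefinedStatisticError,
)
from .genome import GenomeBins, write_bedgraph

__all__ = [
    "binarize_cell",
    "aggregate_profile",
    "classify_early_late",
    "correlate_profiles",
    "order_cells",
    "AggregateRT",
    "ReplicationTimingModel",
    "ReplicationTimingResults",
]


def _best_1d_split(values: np.ndarray) -> tuple:
    """Exact 1-D 2-means: centers (low, high) minimising within-cluster SSE.

    Sorted prefix-sum search over all n-1 splits; O(n log n), fully
    deterministic, always the global optimum.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2:
        raise InsufficientDataError("need >= 2 values to split")
    cs = np.cumsum(v)
    css = np.cumsum(v * v)
    k = np.arange(1, n)  # left cluster size
    left_sse = css[:-1] - cs[:-1] ** 2 / k
    right_sum = cs[-1] - cs[:-1]
    right_sse = (css[-1] - css[:-1]) - right_sum**2 / (n - k)
    best = int(np.argmin(left_sse + right_sse))
    c_low = cs[best] / (best + 1)
    c_high = right_sum[best] / (n - best - 1)
    return float(c_low), float(c_high)


def _em_threshold(
    y: np.ndarray,
    init: tuple | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> float:
    """Posterior decision boundary of a constrained two-Gaussian mixture.

    ``y`` are log copy ratios. The replicated component is constrained
    to sit exactly log(2) above the unreplicated one — the 1x/2x copy
    structure — with a shared variance (multiplicative noise), leaving
    three free parameters (location m, sigma, weight w). EM runs from
    a small set of deterministic inits — ``init`` (typically the
    2-means split, as (m, sigma, w)) plus the two label assignments of
    a single dominant cluster — and the highest-likelihood fit wins,
    guarding against label-swap and tail-catcher local optima. Returns
    the log-ratio boundary where the two posteriors are equal; unlike
    a midpoint
    rule, the boundary shifts with the mixture weight, which keeps
    cells early or late in S phase from being mis-split down the
    middle of their dominant component.
    """
    d = np.log(2.0)
    med = float(np.median(y))
    sigma0 = max(float(np.median(np.abs(y - med))) * 1.4826, 1e-3)

    def run(m, sigma, w):
        for _ in range(max_iter):
            z0 = (y - m) / sigma
            z1 = (y - m - d) / sigma
            log_r0 = np.log(w) - 0.5 * z0**2
            log_r1 = np.log(1 - w) - 0.5 * z1**2
            shift = np.maximum(log_r0, log_r1)
            r0 = np.exp(log_r0 - shift)
            r1 = np.exp(log_r1 - shift)
            g = r0 / (r0 + r1)  # posterior of unreplicated
            w_new = float(np.clip(g.mean(), 1e-3, 1 - 1e-3))
            m_new = float(np.sum(g * y + (1 - g) * (y - d)) / len(y))
            var = float(
                np.sum(g * (y - m_new) ** 2 + (1 - g) * (y - m_new - d) ** 2) / len(y)
            )
            sigma_new = max(np.sqrt(var), 1e-3)
            done = (
                abs(m_new - m) < tol and abs(sigma_new - sigma) < tol and abs(w_new - w) < tol
            )
            m, sigma, w = m_new, sigma_new, w_new
            if done:
                break
        ll = float(
            np.sum(
                np.logaddexp(
                    np.log(w) - 0.5 * ((y - m) / sigma) ** 2,
                    np.log(1 - w) - 0.5 * ((y - m - d) / sigma) ** 2,
                )
                - np.log(sigma)
            )
        )
        return ll, m, sigma, w

    # deterministic inits: the supplied split-based one plus the two
    # label assignments of a single dominant cluster (guards against
    # the label-swap local optimum); ties keep the earlier init
    starts = []
    if init is not None:
        starts.append(init)
    starts += [(med, sigma0, 0.7), (med - d, sigma0, 0.3)]
    fits = [run(*s) for s in starts]
    best = max(range(len(fits)), key=lambda i: (fits[i][0], -i))
    _, m, sigma, w = fits[best]
    # equal-posterior boundary for equal variances
    return m + 0.5 * d + (sigma**2 / d) * np.log(w / (1 - w))


def binarize_cell(
    copy_ratio: np.ndarray,
    min_sep: float = 0.3,
    min_bins: int = 100,
    method: str = "em",
) -> tuple | None:
    """Binary replication states for one S-phase cell.

    Returns ``(states, percent_replicated)`` where ``states`` is a
    per-bin float array with 1.0 = replicated, 0.0 = unreplicated and
    NaN = missing; or ``None`` when the two 2-means cluster centers are
    closer than ``min_sep`` ratio units (non-informative cell, no
    genuine 1x/2x structure).

    method="em" (default)
        Threshold from a two-component mixture on log ratios whose
        components are a fixed factor 2 apart (see ``_em_threshold``);
        robust to cells early or late in S phase, where the replicated
        or unreplicated component dominates.
    method="sse"
        Classic 2-means: threshold at the midpoint of the two cluster
        centers from the exact 1-D SSE optimum. Scale-free and
        assumption-free, but biased for unbalanced mixtures under
        heavy counting noise.
    """
    if method not in ("em", "sse"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    x = np.asarray(copy_ratio, dtype=float)
    finite = np.isfinite(x)
    n = int(finite.sum())
    if n < min_bins:
        raise InsufficientDataError(f"binarize_cell needs >= {min_bins} usable bins, got {n}")
    xf = x[finite]
    c_low, c_high = _best_1d_split(xf)
    if c_high - c_low < min_sep:
        return None
    if method == "sse":
        threshold = 0.5 * (c_low + c_high)
        calls = xf > threshold
    else:
        pos = xf > 0
        y = np.log(xf[pos])
        # seed EM from the 2-means solution: lower center as the
        # unreplicated component location, cluster shares as weight
        mid = 0.5 * (c_low + c_high)
        w0 = float(np.clip((xf[pos] <= mid).mean(), 1e-3, 1 - 1e-3))
        m0 = np.log(max(c_low, 1e-6))
        comp = np.where(xf[pos] <= mid, m0, m0 + np.log(2.0))
        s0 = max(float(np.median(np.abs(y - comp))) * 1.4826, 1e-3)
        calls = np.zeros(xf.shape, dtype=bool)
        calls[pos] = y > _em_threshold(y, init=(m0, s0, w0))
    states = np.full(x.shape, np.nan)
    states[finite] = calls.astype(float)
    percent = float(np.nanmean(states))
    return states, percent


@dataclass
class AggregateRT:
    """Cohort replication profile.

    ``replication_percentage``: per-bin fraction of informative S cells
    replicated, in [0, 1] (NaN where no cell informs the bin).
    ``n_informative``: per-bin count of cells with a non-missing state.
    ``classes``: "early" (> 50 %), "late" (< 50 %), "boundary"
    (exactly 50 %) or "" where undefined.
    """

    replication_percentage: np.ndarray
    n_informative: np.ndarray
    classes: np.ndarray

    def class_counts(self) -> dict:
        vals, counts = np.unique(self.classes[self.classes != ""], return_counts=True)
        return {str(v): int(c) for v, c in zip(vals, counts)}


def aggregate_profile(binary: pd.DataFrame) -> AggregateRT:
    """Per-bin replication percentage over informative S cells.

    ``binary`` is cells x bins with values in {0, 1, NaN}; a missing
    state contributes to neither numerator nor denominator.
    """
    if binary.shape[0] < 1:
        raise DegenerateInputError("no informative cells to aggregate")
    arr = binary.to_numpy(dtype=float)
    n_inf = np.isfinite(arr).sum(axis=0)
    k = np.nansum(arr, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_inf > 0, k / np.maximum(n_inf, 1), np.nan)
    classes = classify_early_late_counts(k, n_inf)
    return AggregateRT(replication_percentage=frac, n_informative=n_inf, classes=classes)


def classify_early_late_counts(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Early/late/boundary from integer counts, exact at the 50 % tie."""
    classes = np.full(k.shape, "", dtype=object)
    informative = n > 0
    two_k = 2 * k
    classes[informative & (two_k > n)] = "early"
    classes[informative & (two_k < n)] = "late"
    classes[informative & (two_k == n)] = "boundary"
    return classes


def classify_early_late(aggregate: AggregateRT) -> np.ndarray:
    """Per-bin class from an AggregateRT (early > 0.5, late < 0.5,
    boundary at exactly 0.5; both defining inequalities are strict)."""
    return aggregate.classes


def correlate_profiles(
    prof_a: np.ndarray,
    prof_b: np.ndarray,
    bins: GenomeBins | None = None,
    scope: str | None = None,
    min_bins: int = 10,
) -> tuple:
    """Pearson r between two per-bin replication profiles.

    ``scope`` restricts to one chromosome (requires ``bins``); only
    bins non-missing in both profiles enter. Returns (r, n_bins_used).
    """
    a = np.asarray(prof_a, dtype=float)
    b = np.asarray(prof_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError("profiles must align")
    sel = np.isfinite(a) & np.isfinite(b)
    if scope is not None:
        if bins is None:
            raise InvalidArgumentError("chromosome scope requires bins")
        chrom_sel = np.zeros(a.shape, dtype=bool)
        chrom_sel[bins.chrom_slice(scope)] = True
        sel &= chrom_sel
    if bins is not None:
        sel &= bins.unmasked
    n = int(sel.sum())
    if n < min_bins:
        raise InsufficientDataError(f"need >= {min_bins} shared bins, got {n}")
    if np.std(a[sel]) == 0 or np.std(b[sel]) == 0:
        raise UndefinedStatisticError("zero variance in a profile")
    r = float(sps.pearsonr(a[sel], b[sel]).statistic)
    return r, n


def order_cells(percent_replicated: pd.Series) -> pd.Index:
    """Cells in ascending order of percent genome replicated.

    Stable sort; ties broken lexicographically by cell id.
    """
    df = pd.DataFrame({"p": percent_replicated, "cid": percent_replicated.index.astype(str)})
    return df.sort_values(["p", "cid"], kind="mergesort").index


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class ReplicationTimingModel:
    """Replication-timing model over a cohort of S-phase cells.

    Parameters
    ----------
    ratios : DataFrame (cells x bins) or mapping cell_id -> per-bin array
        Corrected copy ratios of S-phase cells (NaN = masked bin).
    bins : GenomeBins
    min_sep : float
        Minimum separation of the two 2-means centers (ratio units) for
        a cell to count as informative.
    min_bins : int
        Minimum usable bins per cell.
    """

    def __init__(self, ratios, bins: GenomeBins, min_sep: float = 0.3, min_bins: int = 100):
        if isinstance(ratios, pd.DataFrame):
            self.ratios = ratios
        else:
            self.ratios = pd.DataFrame(
                {cid: np.asarray(x, dtype=float) for cid, x in ratios.items()}
            ).T
        if self.ratios.shape[1] != bins.n_bins:
            raise InvalidArgumentError("ratio matrix width must equal number of bins")
        self.bins = bins
        self.min_sep = float(min_sep)
        self.min_bins = int(min_bins)

    def fit(self) -> "ReplicationTimingResults":
        masked = self.bins.mask
        states_rows = {}
        percents = {}
        non_informative = []
        for cid, row in self.ratios.iterrows():
            x = row.to_numpy(dtype=float).copy()
            x[masked] = np.nan
            out = binarize_cell(x, min_sep=self.min_sep, min_bins=self.min_bins)
            if out is None:
                non_informative.append(cid)
                continue
            states, pct = out
            states_rows[cid] = states
            percents[cid] = pct
        if not states_rows:
            raise DegenerateInputError("no informative S cells")
        binary = pd.DataFrame(states_rows).T
        binary.columns = range(self.bins.n_bins)
        percent = pd.Series(percents, name="percent_replicated")
        aggregate = aggregate_profile(binary)
        return ReplicationTimingResults(
            model=self,
            binary=binary,
            percent_replicated=percent,
            aggregate=aggregate,
            non_informative=tuple(non_informative),
        )


@dataclass
class ReplicationTimingResults:
    """Fitted replication-timing profile and per-cell binary states."""

    model: ReplicationTimingModel
    binary: pd.DataFrame  # informative cells x bins, values {0,1,NaN}
    percent_replicated: pd.Series
    aggregate: AggregateRT
    non_informative: tuple

    @property
    def bins(self) -> GenomeBins:
        return self.model.bins

    def ordered_cells(self) -> pd.Index:
        return order_cells(self.percent_replicated)

    def ordered_binary(self) -> pd.DataFrame:
        """Cells ordered by percent genome replicated (display order)."""
        return self.binary.loc[self.ordered_cells()]

    def correlate(self, other, scope: str | None = None) -> tuple:
        prof = other.aggregate.replication_percentage if hasattr(other, "aggregate") else other
        return correlate_profiles(
            self.aggregate.replication_percentage, prof, bins=self.bins, scope=scope
        )

    def to_bedgraph(self, path) -> None:
        write_bedgraph(self.aggregate.replication_percentage, self.bins, path)

    def classes_bed(self, path) -> None:
        """BED4 of early/late/boundary bin classes."""
        b = self.bins
        with open(path, "w") as fh:
            for i in range(b.n_bins):
                cls = self.aggregate.classes[i]
                if b.mask[i] or cls == "":
                    continue
                fh.write(
                    f"{b.chrom_names[b.chrom_index[i]]}\t{b.starts[i]}\t{b.ends[i]}\t{cls}\n"
                )

    def binary_table(self) -> pd.DataFrame:
        cols = [f"{c}:{s}-{e}" for c, s, e in self.bins.iter_bins()]
        out = self.ordered_binary().copy()
        out.columns = cols
        return out

    def summary(self) -> str:
        counts = self.aggregate.class_counts()
        pct = self.percent_replicated
        lines = [
            "Replication timing summary",
            "==========================",
            f"informative S cells : {len(self.binary)}",
            f"non-informative     : {len(self.non_informative)}",
            f"bins (unmasked)     : {int(self.bins.unmasked.sum())}",
            f"early bins          : {counts.get('early', 0)}",
            f"late bins           : {counts.get('late', 0)}",
            f"boundary bins       : {counts.get('boundary', 0)}",
            f"percent replicated  : median {pct.median():.3f}"
            f" (range {pct.min():.3f}-{pct.max():.3f})",
        ]
        return "\n".join(lines)
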