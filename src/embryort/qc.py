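"""Per-cell quality control: G1-reference normalisation, GC/amplification
correction, MAD scoring and cell-phase classification.

A non-replicating (G1) reference profile flattens bin-specific biases
shared across cells (mappability, amplification efficiency); per-cell
GC correction removes the residual cell-specific GC trend. The MAD
(median absolute deviation from the median) of the corrected copy
ratios separates phases: flat G1 profiles score low, bimodal 1x/2x
S-phase profiles score high. Threshold defaults follow the convention
of low (< 0.3) for G1 and moderate (0.4–0.8) for S; because the MAD
scale depends on depth, bin size and amplification protocol, a
data-driven calibration (``calibrate_phase_thresholds``) is provided
and used by the pipeline on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InsufficientDataError, InvalidArgumentError
from .genome import GenomeBins

__all__ = [
    "CellProfile",
    "PhaseThresholds",
    "build_g1_reference",
    "normalize_to_reference",
    "gc_correct",
    "gc_trend",
    "mad_score",
    "classify_phase",
    "calibrate_phase_thresholds",
    "thresholds_from_reference",
    "qc_cells",
    "qc_table",
]

#: Conventional MAD thresholds: G1 below ``g1_max``; S within
#: [``s_min``, ``s_max``]; everything else excluded (the [g1_max, s_min)
#: gray zone and the uninterpretable > s_max tail).
@dataclass(frozen=True)
class PhaseThresholds:
    g1_max: float = 0.3
    s_min: float = 0.4
    s_max: float = 0.8


DEFAULT_THRESHOLDS = PhaseThresholds()


@dataclass
class CellProfile:
    """One cell's QC state: raw counts, corrected copy ratios, MAD, phase."""

    cell_id: str
    raw_counts: np.ndarray
    copy_ratio: np.ndarray  # NaN on masked / unusable bins; ~1 = unreplicated
    mad: float
    phase: str  # "G1" | "S" | "excluded"


def build_g1_reference(counts: np.ndarray, method: str = "mean") -> np.ndarray:
    """Per-bin reference from non-replicating cells.

    Each cell is depth-normalised (counts / total) first so deep cells
    do not dominate; the reference is the per-bin mean (default) or
    median across cells, rescaled to sum to 1.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if counts.shape[0] < 1:
        raise InvalidArgumentError("reference requires >= 1 cell")
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise DegenerateInputError("reference contains an all-zero cell")
    norm = counts / totals
    if method == "mean":
        ref = norm.mean(axis=0)
    elif method == "median":
        ref = np.median(norm, axis=0)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    s = ref.sum()
    if s == 0:
        raise DegenerateInputError("reference is all zero")
    return ref / s


def normalize_to_reference(
    cell_counts: np.ndarray,
    g1_reference: np.ndarray,
    bins: GenomeBins,
) -> np.ndarray:
    """Depth-normalised copy ratio x_b = (c_b / sum c) / (r_b / sum r).

    Computed over unmasked bins; bins with zero reference signal are
    masked for this cell (NaN). A copy ratio of 1 corresponds to the
    unreplicated baseline.
    """
    c = np.asarray(cell_counts, dtype=float)
    r = np.asarray(g1_reference, dtype=float)
    if c.shape != (bins.n_bins,) or r.shape != (bins.n_bins,):
        raise InvalidArgumentError("counts/reference length must match bins")
    usable = bins.unmasked & (r > 0)
    c_tot = c[usable].sum()
    if c_tot == 0:
        raise DegenerateInputError("cell has zero reads on usable bins")
    r_tot = r[usable].sum()
    x = np.full(bins.n_bins, np.nan)
    x[usable] = (c[usable] / c_tot) / (r[usable] / r_tot)
    return x


def gc_trend(copy_ratio: np.ndarray, gc: np.ndarray, span: float = 0.25) -> np.ndarray:
    """Per-bin local-median GC trend of a (unimodal) copy-ratio profile.

    Usable bins are split into ``round(1 / span)`` GC-quantile strata;
    the trend is the stratum median, normalised to overall median 1.
    Estimate this on non-replicating (G1/reference) profiles only: on a
    bimodal S-phase profile a stratum median snaps unstably to one of
    the two copy modes and the "trend" would scramble the 1x/2x signal.
    Returns NaN where the ratio or GC is missing.
    """
    x = np.asarray(copy_ratio, dtype=float)
    g = np.asarray(gc, dtype=float)
    if x.shape != g.shape:
        raise InvalidArgumentError("copy_ratio and gc must align")
    if not 0 < span <= 1:
        raise InvalidArgumentError(f"span must be in (0, 1], got {span}")
    usable = np.isfinite(x) & np.isfinite(g)
    n = int(usable.sum())
    if n < 30:
        raise InsufficientDataError(f"gc trend needs >= 30 usable bins, got {n}")
    trend = np.full_like(x, np.nan)
    gu, xu = g[usable], x[usable]
    tu = np.ones_like(xu)
    if np.ptp(gu) > 0:
        n_strata = max(2, int(round(1.0 / span)))
        edges = np.quantile(gu, np.linspace(0, 1, n_strata + 1)[1:-1])
        strata = np.digitize(gu, edges)
        for s in np.unique(strata):
            sel = strata == s
            med = np.median(xu[sel])
            if med > 0:
                tu[sel] = med
    overall = np.median(xu / tu)
    trend[usable] = tu * (overall if overall > 0 else 1.0)
    return trend


def gc_correct(copy_ratio: np.ndarray, gc: np.ndarray, span: float = 0.25) -> np.ndarray:
    """Divide out the local GC trend and rescale to median 1.

    The trend is a local-median regression of the copy ratio on GC:
    usable bins are split into ``round(1 / span)`` GC-quantile strata
    and each value is divided by its stratum median. This robust,
    piecewise-constant trend is exactly idempotent — a second
    application returns the input unchanged — which a smoother local
    fit would not be. Bins with NaN ratio or NaN GC pass through as NaN.
    """
    x = np.asarray(copy_ratio, dtype=float)
    g = np.asarray(gc, dtype=float)
    if x.shape != g.shape:
        raise InvalidArgumentError("copy_ratio and gc must align")
    if not 0 < span <= 1:
        raise InvalidArgumentError(f"span must be in (0, 1], got {span}")
    usable = np.isfinite(x) & np.isfinite(g)
    n = int(usable.sum())
    if n < 30:
        raise InsufficientDataError(f"gc_correct needs >= 30 usable bins, got {n}")
    out = np.full_like(x, np.nan)
    gu, xu = g[usable], x[usable]
    if np.ptp(gu) == 0:
        corrected = xu
    else:
        n_strata = max(2, int(round(1.0 / span)))
        # quantile edges; digitize is stable under the idempotence
        # requirement because strata depend only on gc, never on x
        edges = np.quantile(gu, np.linspace(0, 1, n_strata + 1)[1:-1])
        strata = np.digitize(gu, edges)
        trend = np.ones_like(xu)
        for s in np.unique(strata):
            sel = strata == s
            med = np.median(xu[sel])
            if med > 0:
                trend[sel] = med
        corrected = xu / trend
    med = np.median(corrected)
    if med <= 0:
        raise DegenerateInputError("corrected profile has non-positive median")
    out[usable] = corrected / med
    return out


def mad_score(copy_ratio: np.ndarray) -> float:
    """Median absolute deviation of copy ratios from their median.

    The raw MAD, without the 1.4826 normal-consistency factor: flat G1
    profiles give values near the noise floor, bimodal S profiles
    larger values.
    """
    x = np.asarray(copy_ratio, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise InsufficientDataError(f"mad_score needs >= 2 bins, got {x.size}")
    return float(np.median(np.abs(x - np.median(x))))


def classify_phase(mad: float, thresholds: PhaseThresholds = DEFAULT_THRESHOLDS) -> str:
    """G1 if mad < g1_max; S if s_min <= mad <= s_max; else excluded.

    Cells in the gray zone [g1_max, s_min) are neither confidently flat
    nor confidently bimodal; cells above s_max are uninterpretable.
    """
    if mad < 0:
        raise InvalidArgumentError(f"mad must be >= 0, got {mad}")
    if mad < thresholds.g1_max:
        return "G1"
    if thresholds.s_min <= mad <= thresholds.s_max:
        return "S"
    return "excluded"


def thresholds_from_reference(reference_mads, fence: float = 3.0) -> PhaseThresholds:
    """Phase thresholds calibrated on a non-replicating reference cohort.

    The G1/S cut is the Tukey far-out fence of the reference cells' own
    MAD scores (Q3 + ``fence`` * IQR): any assay cell whose variability
    exceeds what non-replicating cells exhibit is called S. This
    mirrors calibrating the MAD scale on an external G1 reference
    cohort rather than asserting fixed cutoffs, which is necessary
    because the MAD scale depends on depth, bin size and amplification
    noise. No gray zone; ``s_max`` is unbounded.
    """
    m = np.asarray(list(reference_mads), dtype=float)
    m = m[np.isfinite(m)]
    if m.size < 4:
        raise InsufficientDataError("reference calibration needs >= 4 cells")
    q1, q3 = np.percentile(m, [25, 75])
    cut = float(q3 + fence * (q3 - q1))
    return PhaseThresholds(g1_max=cut, s_min=cut, s_max=float("inf"))


def calibrate_phase_thresholds(mad_scores, s_max_factor: float = 4.0) -> PhaseThresholds:
    """Data-driven G1/S threshold from the cohort's MAD distribution.

    Splits the MAD scores at the exact two-cluster 1-D SSE optimum
    (2-means) and places both g1_max and s_min at the midpoint of the
    cluster centers, so no cell falls in a gray zone; s_max is set to
    ``s_max_factor`` times the upper center to reject only extreme
    outliers. Intended for cohorts known to contain both phases.
    """
    from .rt import _best_1d_split  # exact 1-D 2-means shared with binarisation

    m = np.asarray(list(mad_scores), dtype=float)
    m = m[np.isfinite(m)]
    if m.size < 4:
        raise InsufficientDataError("calibration needs >= 4 cells")
    c_low, c_high = _best_1d_split(m)
    cut = 0.5 * (c_low + c_high)
    return PhaseThresholds(g1_max=cut, s_min=cut, s_max=max(c_high * s_max_factor, cut))


def qc_cells(
    counts: np.ndarray,
    cell_ids,
    bins: GenomeBins,
    g1_reference: np.ndarray | None = None,
    reference_counts: np.ndarray | None = None,
    thresholds: PhaseThresholds | None = None,
    span: float = 0.25,
    calibrate: bool = False,
    gc_mode: str = "auto",
) -> list:
    """Run the full QC chain on a cohort; returns list of CellProfile.

    ``reference_counts`` — a counts matrix of an external
    non-replicating (G1) cohort, analogous to the G1 ES-cell reference
    datasets used to even copy numbers across the genome — is the
    recommended input: the per-bin reference and the phase thresholds
    (``thresholds_from_reference``) are both derived from it. Without
    it, an explicit ``g1_reference`` can be given, or the per-bin mean
    over all assay cells is used as a fallback (adequate only when most
    cells are non-replicating, since S cells leak replication signal
    into such a reference). ``calibrate=True`` (without a reference
    cohort) calibrates thresholds from the assay cohort's own MAD
    distribution by 2-means.

    GC handling (``gc_mode``): "reference" estimates the residual GC
    trend once from the reference cohort's own (flat) ratio profiles
    and divides that fixed trend out of every assay cell — safe for
    bimodal S-phase profiles, whose own stratum medians would snap
    between the 1x and 2x modes and destroy the replication signal;
    "per_cell" applies ``gc_correct`` to each cell individually (only
    sound for cohorts of flat profiles); "none" skips the step.
    "auto" (default) means "reference" when a reference cohort is
    available, else "per_cell".
    """
    counts = np.atleast_2d(np.asarray(counts))
    if gc_mode not in ("auto", "reference", "per_cell", "none"):
        raise InvalidArgumentError(f"unknown gc_mode {gc_mode!r}")
    if gc_mode == "auto":
        gc_mode = "reference" if reference_counts is not None else "per_cell"
    if gc_mode == "reference" and reference_counts is None:
        raise InvalidArgumentError("gc_mode='reference' requires reference_counts")
    if bins.gc is None:
        gc_mode = "none"

    ref_trend = None

    def _chain(c):
        x = normalize_to_reference(c, g1_reference, bins)
        if gc_mode == "per_cell":
            x = gc_correct(x, bins.gc, span=span)
        elif gc_mode == "reference" and ref_trend is not None:
            with np.errstate(invalid="ignore", divide="ignore"):
                x = x / ref_trend
            med = np.nanmedian(x)
            if med > 0:
                x = x / med
        return x

    if reference_counts is not None:
        reference_counts = np.atleast_2d(np.asarray(reference_counts))
        g1_reference = build_g1_reference(reference_counts)
        if gc_mode == "reference":
            ref_ratios = np.vstack(
                [
                    normalize_to_reference(reference_counts[i], g1_reference, bins)
                    for i in range(reference_counts.shape[0])
                ]
            )
            ref_trend = gc_trend(np.nanmean(ref_ratios, axis=0), bins.gc, span=span)
        if thresholds is None:
            ref_mads = [mad_score(_chain(reference_counts[i])) for i in range(reference_counts.shape[0])]
            thresholds = thresholds_from_reference(ref_mads)
    elif g1_reference is None:
        g1_reference = build_g1_reference(counts)
    ratios = []
    mads = []
    for row in range(counts.shape[0]):
        x = _chain(counts[row])
        ratios.append(x)
        mads.append(mad_score(x))
    if thresholds is None:
        thresholds = calibrate_phase_thresholds(mads) if calibrate else DEFAULT_THRESHOLDS
    return [
        CellProfile(
            cell_id=str(cid),
            raw_counts=counts[row],
            copy_ratio=ratios[row],
            mad=mads[row],
            phase=classify_phase(mads[row], thresholds),
        )
        for row, cid in enumerate(cell_ids)
    ]


def qc_table(profiles) -> pd.DataFrame:
    """Per-cell QC summary (cell_id, total_reads, mad, phase)."""
    return pd.DataFrame(
        {
            "cell_id": [p.cell_id for p in profiles],
            "total_reads": [int(np.sum(p.raw_counts)) for p in profiles],
            "mad": [p.mad for p in profiles],
            "phase": [p.phase for p in profiles],
        }
    )
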