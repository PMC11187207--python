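"""DNA-fiber assay arithmetic: fork speed and inter-origin distance.

Stretched DNA fibers are measured in micrometres and converted to
kilobases with the standard stretching factor of 2.59 kb/um. Fork
speed is the labelled-track length divided by the pulse duration;
inter-origin distances are the gaps between adjacent origin midpoints
along a fiber (origins are supplied as midpoints of divergent
sister-fork pairs). Group comparisons delegate to the rank/ANOVA tests
in :mod:`embryort.enrich`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrich import mann_whitney, one_way_anova
from .errors import InvalidArgumentError

__all__ = [
    "KB_PER_UM",
    "FiberMeasurement",
    "um_to_kb",
    "fork_speed",
    "inter_origin_distances",
    "summarize_groups",
    "read_fiber_tsv",
]

#: DNA stretching factor for spread fibers, kb per micrometre.
KB_PER_UM = 2.59

#: Default labelling pulse duration in minutes.
DEFAULT_PULSE_MIN = 30.0


@dataclass
class FiberMeasurement:
    """One measured fiber: label track length(s), pulse, origin positions."""

    fiber_id: str
    group: str
    length_um: float  # first-pulse track length
    second_length_um: float | None = None  # optional second pulse
    pulse_min: float = DEFAULT_PULSE_MIN
    origin_positions_um: list = field(default_factory=list)

    def __post_init__(self):
        if self.length_um < 0 or (self.second_length_um or 0) < 0:
            raise InvalidArgumentError("track lengths must be >= 0")
        if self.pulse_min <= 0:
            raise InvalidArgumentError("pulse duration must be positive")


def um_to_kb(length_um: float, factor_kb_per_um: float = KB_PER_UM):
    """Convert a fiber length in micrometres to kilobases (exact product)."""
    arr = np.asarray(length_um, dtype=float)
    if np.any(arr < 0):
        raise InvalidArgumentError("length must be >= 0")
    if factor_kb_per_um <= 0:
        raise InvalidArgumentError("conversion factor must be positive")
    out = arr * factor_kb_per_um
    return float(out) if np.isscalar(length_um) else out


def fork_speed(
    track_um: float,
    pulse_min: float = DEFAULT_PULSE_MIN,
    factor_kb_per_um: float = KB_PER_UM,
):
    """Replication fork speed in kb/min from a single labelled track."""
    if pulse_min <= 0:
        raise InvalidArgumentError("pulse duration must be positive")
    kb = um_to_kb(track_um, factor_kb_per_um)
    return kb / pulse_min


def inter_origin_distances(
    origin_positions_um,
    factor_kb_per_um: float = KB_PER_UM,
) -> tuple:
    """Pooled adjacent inter-origin distances (kb) and their median.

    ``origin_positions_um`` is an iterable of per-fiber position lists
    (um along the fiber, any order; sorted internally). Fibers with
    fewer than two origins contribute nothing. Returns
    ``(distances, median)``; median is NaN when no distance exists.
    """
    distances = []
    for fiber in origin_positions_um:
        pos = np.sort(np.asarray(list(fiber), dtype=float))
        if pos.size >= 2:
            distances.extend(np.diff(pos) * factor_kb_per_um)
    distances = np.asarray(distances, dtype=float)
    median = float(np.median(distances)) if distances.size else float("nan")
    return distances, median


def summarize_groups(
    measurements,
    metric: str = "fork_speed",
    test: str = "mann_whitney",
    factor_kb_per_um: float = KB_PER_UM,
) -> pd.DataFrame:
    """Per-group medians and a between-group test.

    metric="fork_speed": one value per fiber (first-pulse track).
    metric="inter_origin": distances pooled across a group's fibers.
    test="mann_whitney" needs exactly 2 groups; "anova" >= 2; ``None``
    skips testing. Returns a DataFrame of group, n, median plus the
    test statistic and p value attached as ``.attrs``.
    """
    if metric not in ("fork_speed", "inter_origin"):
        raise InvalidArgumentError(f"unknown metric {metric!r}")
    by_group: dict = {}
    for m in measurements:
        by_group.setdefault(m.group, []).append(m)
    values = {}
    for group, ms in by_group.items():
        if metric == "fork_speed":
            values[group] = np.array(
                [fork_speed(m.length_um, m.pulse_min, factor_kb_per_um) for m in ms]
            )
        else:
            d, _ = inter_origin_distances(
                [m.origin_positions_um for m in ms], factor_kb_per_um
            )
            values[group] = d
    rows = [
        {"group": g, "n": int(v.size), "median": float(np.median(v)) if v.size else float("nan")}
        for g, v in values.items()
    ]
    out = pd.DataFrame(rows)
    if test is not None:
        groups = list(values.values())
        if len(groups) < 2:
            raise InvalidArgumentError("testing requires >= 2 groups")
        if test == "mann_whitney":
            if len(groups) != 2:
                raise InvalidArgumentError("mann_whitney requires exactly 2 groups")
            stat, p = mann_whitney(groups[0], groups[1])
            out.attrs.update(test="mann_whitney", statistic=stat, p_value=p)
        elif test == "anova":
            stat, p = one_way_anova(groups)
            out.attrs.update(test="anova", statistic=stat, p_value=p)
        else:
            raise InvalidArgumentError(f"unknown test {test!r}")
    return out


def read_fiber_tsv(path) -> list:
    """Measurements from TSV: fiber_id, group, length_um[, second_length_um]
    [, pulse_min][, origin_positions_um (semicolon-separated)]."""
    df = pd.read_csv(path, sep="\t")
    required = {"fiber_id", "group", "length_um"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"fiber TSV missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        origins = []
        raw = getattr(row, "origin_positions_um", None)
        if isinstance(raw, str) and raw.strip():
            origins = [float(v) for v in raw.split(";") if v.strip()]
        out.append(
            FiberMeasurement(
                fiber_id=str(row.fiber_id),
                group=str(row.group),
                length_um=float(row.length_um),
                second_length_um=float(v) if (v := getattr(row, "second_length_um", None)) is not None and np.isfinite(v) else None,
                pulse_min=float(getattr(row, "pulse_min", DEFAULT_PULSE_MIN) or DEFAULT_PULSE_MIN),
                origin_positions_um=origins,
            )
        )
    return out
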