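"""Growth-event classification and exploration dynamics.

Between two consecutive trinarized frames every in-arena pixel undergoes at
most one event: primary growth (unexplored -> slime, a first visit),
secondary growth (mucus -> slime, a revisit), or refinement (slime -> mucus,
a withdrawal).  These satisfy an exact area balance on every interval::

    slime_area(t) - slime_area(t-1) = #primary + #secondary - #refinement

The extent of growth of an interval is, for each grown pixel, the Euclidean
distance to the nearest pixel that was slime in the previous frame (exact
distance transform); the migration rate is the maximum extent divided by the
sampling interval, in mm/min.  The expansion region is the band of non-slime
arena pixels within that maximum extent of the previous slime set, and the
observed vs expected secondary-growth fractions over it quantify whether the
organism prefers previously explored substrate (mucus) to virgin substrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .labels import Event, Label
from .segmentation import TrinarizedFrame

__all__ = [
    "TransitionMap",
    "CoverageSeries",
    "classify_transitions",
    "coverage_fractions",
    "growth_extents",
    "migration_rate",
    "expansion_region",
    "secondary_growth_bias",
    "accumulate",
]


@dataclass
class TransitionMap:
    """Per-pixel growth events for the interval ending at frame ``interval_index``."""

    events: np.ndarray
    interval_index: int
    arena: "object"

    def event_mask(self, event: Event) -> np.ndarray:
        return self.events == event

    @property
    def growth(self) -> np.ndarray:
        """Pixels where growth of either kind occurred."""
        return (self.events == Event.PRIMARY) | (self.events == Event.SECONDARY)


def classify_transitions(prev: TrinarizedFrame, curr: TrinarizedFrame) -> TransitionMap:
    """Classify each pixel's transition between two consecutive frames."""
    if curr.frame_index != prev.frame_index + 1:
        raise ValueError(
            f"frames are not consecutive: {prev.frame_index} -> {curr.frame_index}"
        )
    if prev.arena is not curr.arena and not np.array_equal(prev.arena.mask, curr.arena.mask):
        raise ValueError("frames refer to different arenas")
    p, c = prev.labels, curr.labels
    ev = np.zeros(p.shape, dtype=np.uint8)
    inside = prev.arena.mask
    ev[inside & (p == Label.UNEXPLORED) & (c == Label.SLIME)] = Event.PRIMARY
    ev[inside & (p == Label.MUCUS) & (c == Label.SLIME)] = Event.SECONDARY
    ev[inside & (p == Label.SLIME) & (c == Label.MUCUS)] = Event.REFINEMENT
    return TransitionMap(ev, curr.frame_index, prev.arena)


def coverage_fractions(frame: TrinarizedFrame) -> tuple[float, float, float]:
    """(slime, mucus, unexplored) fractions of the arena; they sum to 1."""
    n = frame.arena.n_px
    return (
        frame.slime.sum() / n,
        frame.mucus.sum() / n,
        frame.unexplored.sum() / n,
    )


def _distance_to_slime_px(prev_slime: np.ndarray) -> np.ndarray:
    """Euclidean distance (px) from every pixel to the nearest previous-slime pixel."""
    if not prev_slime.any():
        raise ValueError("previous slime mask is empty — organism lost")
    return ndimage.distance_transform_edt(~prev_slime)


def growth_extents(
    events: TransitionMap, prev_slime: np.ndarray, mm_per_px: float
) -> np.ndarray:
    """Distances (mm) from each grown pixel to the nearest previous slime pixel."""
    dist = _distance_to_slime_px(np.asarray(prev_slime, dtype=bool))
    return dist[events.growth] * mm_per_px


def migration_rate(extents_mm: np.ndarray, interval_min: float) -> float:
    """Maximum extent of growth over the sampling interval, mm/min (0 if no growth)."""
    if interval_min <= 0:
        raise ValueError("interval_min must be > 0")
    extents_mm = np.asarray(extents_mm)
    if extents_mm.size == 0:
        return 0.0
    return float(extents_mm.max()) / interval_min


def expansion_region(prev: TrinarizedFrame, offset_mm: float) -> np.ndarray:
    """Band of non-slime arena pixels within ``offset_mm`` of the previous slime set.

    ``offset_mm`` is the interval's maximum growth extent (migration rate
    times interval).  An offset of 0 yields an empty region; an offset larger
    than the arena saturates to all non-slime arena pixels.
    """
    if offset_mm < 0:
        raise ValueError("offset_mm must be >= 0")
    prev_slime = prev.slime
    dist = _distance_to_slime_px(prev_slime)
    offset_px = offset_mm / prev.arena.mm_per_px
    return prev.arena.mask & ~prev_slime & (dist <= offset_px)


def secondary_growth_bias(
    events: TransitionMap, region: np.ndarray, prev: TrinarizedFrame
) -> tuple[float, float]:
    """Observed and expected secondary-growth fractions for one interval.

    observed = #secondary / (#secondary + #primary) — the realized share of
    growth that lands on mucus; expected = share of mucus among the pixels of
    the expansion region, i.e. the share that uniformly random growth within
    the region would produce.  Either is NaN when its denominator is zero.
    """
    n_sec = int(events.event_mask(Event.SECONDARY).sum())
    n_pri = int(events.event_mask(Event.PRIMARY).sum())
    observed = n_sec / (n_sec + n_pri) if (n_sec + n_pri) > 0 else float("nan")
    n_region = int(region.sum())
    n_mucus = int((region & prev.mucus).sum())
    expected = n_mucus / n_region if n_region > 0 else float("nan")
    return observed, expected


def accumulate(
    frames: list[TrinarizedFrame],
    interval_min: float,
    pool_window_min: float = 60.0,
) -> "CoverageSeries":
    """Assemble per-frame coverage and per-interval growth metrics into one table.

    One row per frame; interval quantities on row ``t`` describe the interval
    from frame ``t-1`` to ``t`` (row 0 has no interval; it carries the initial
    plasmodium footprint as primary coverage, so cumulative primary growth
    equals the explored fraction at every time).  Areas are arena fractions,
    so cumulative secondary growth may exceed 1 while cumulative primary
    growth cannot.  Observed/expected secondary fractions are also
    pooled over a sliding window (default 1 h) because single 5-min intervals
    are often degenerate.
    """
    if len(frames) < 1:
        raise ValueError("no frames")
    idx = [f.frame_index for f in frames]
    if idx != list(range(idx[0], idx[0] + len(frames))):
        raise ValueError("frame indices have gaps or are out of order")

    arena = frames[0].arena
    n_px = arena.n_px
    rows = []
    ev_counts = []  # (n_primary, n_secondary, n_refine, n_region, n_region_mucus)
    for t, f in enumerate(frames):
        fs, fm, fu = coverage_fractions(f)
        row = {
            "frame": f.frame_index,
            "time_min": t * interval_min,
            "frac_slime": fs,
            "frac_mucus": fm,
            "frac_unexplored": fu,
        }
        if t == 0:
            # the initial plasmodium footprint counts as first-visit coverage,
            # so cumulative primary growth equals the explored fraction exactly
            row.update(
                primary=fs, secondary=0.0, refinement=0.0,
                migration_rate_mm_min=np.nan,
                observed_secondary=np.nan, expected_secondary=np.nan,
            )
            ev_counts.append((0, 0, 0, 0, 0))
        else:
            prev = frames[t - 1]
            tm = classify_transitions(prev, f)
            n_pri = int(tm.event_mask(Event.PRIMARY).sum())
            n_sec = int(tm.event_mask(Event.SECONDARY).sum())
            n_ref = int(tm.event_mask(Event.REFINEMENT).sum())
            if prev.slime.any():
                ext = growth_extents(tm, prev.slime, arena.mm_per_px)
                rate = migration_rate(ext, interval_min)
                region = expansion_region(prev, rate * interval_min)
            else:
                rate = 0.0
                region = np.zeros_like(arena.mask)
            obs, exp = secondary_growth_bias(tm, region, prev)
            row.update(
                primary=n_pri / n_px, secondary=n_sec / n_px, refinement=n_ref / n_px,
                migration_rate_mm_min=rate,
                observed_secondary=obs, expected_secondary=exp,
            )
            ev_counts.append(
                (n_pri, n_sec, n_ref, int(region.sum()), int((region & prev.mucus).sum()))
            )
        rows.append(row)

    df = pd.DataFrame(rows)
    for col in ("primary", "secondary", "refinement"):
        df[f"cum_{col}"] = df[col].cumsum()

    # sliding-window pooling of the growth-bias counts
    counts = pd.DataFrame(
        ev_counts, columns=["n_pri", "n_sec", "n_ref", "n_region", "n_region_mucus"]
    )
    w = max(1, int(round(pool_window_min / interval_min)))
    roll = counts.rolling(w, min_periods=1).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        df["observed_secondary_pooled"] = roll["n_sec"] / (roll["n_sec"] + roll["n_pri"])
        df["expected_secondary_pooled"] = roll["n_region_mucus"] / roll["n_region"]
    return CoverageSeries(df, interval_min)


@dataclass
class CoverageSeries:
    """Per-frame/per-interval coverage, growth, and migration table."""

    table: pd.DataFrame
    interval_min: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def final_explored_fraction(self) -> float:
        last = self.table.iloc[-1]
        return float(last["frac_slime"] + last["frac_mucus"])
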