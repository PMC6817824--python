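"""Attractant-spot geometry, distance tracking, and time-to-contact curves.

In spot experiments the plasmodium starts at a distance from a circular
glucose (attractant) spot, optionally with a salt (repellent) spot in
between.  The tracked quantity is the minimum distance from the slime
contour to the glucose spot's edge (0 once they touch), and across
replicates the empirical survival-style curve P(t): the fraction of
replicates that have not yet reached the spot at time t.  Replicates that
never reach it within the recording are censored at the final time and count
as not-reached throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .frames_io import ArenaMask

__all__ = [
    "Spot",
    "SpotLayout",
    "SurvivalCurve",
    "distance_to_spot",
    "time_to_contact",
    "survival_curve",
]

SPOT_KINDS = ("glucose", "salt", "origin")


@dataclass
class Spot:
    """A circular spot: attractant (glucose), repellent (salt), or the start disc."""

    center_px: tuple[float, float]
    radius_px: float
    kind: str = "glucose"

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("spot radius must be > 0")
        if self.kind not in SPOT_KINDS:
            raise ValueError(f"spot kind must be one of {SPOT_KINDS}")


@dataclass
class SpotLayout:
    """Spots of one arena; validated to lie inside it."""

    spots: list[Spot] = field(default_factory=list)

    def validate(self, arena: ArenaMask) -> None:
        r0, c0 = arena.center_px
        for s in self.spots:
            d = np.hypot(s.center_px[0] - r0, s.center_px[1] - c0)
            if d + s.radius_px > arena.radius_px:
                raise ValueError(f"spot at {s.center_px} extends outside the arena")

    @property
    def glucose(self) -> Spot:
        for s in self.spots:
            if s.kind == "glucose":
                return s
        raise ValueError("layout defines no glucose spot")


def distance_to_spot(
    slime_mask: np.ndarray, layout: SpotLayout, mm_per_px: float, kind: str = "glucose"
) -> float:
    """Minimum distance (mm) from the slime to the edge of a spot, clamped at 0."""
    slime_mask = np.asarray(slime_mask, dtype=bool)
    if not slime_mask.any():
        raise ValueError("empty slime mask")
    spot = layout.glucose if kind == "glucose" else next(
        s for s in layout.spots if s.kind == kind
    )
    rows, cols = np.nonzero(slime_mask)
    d_center = np.hypot(rows - spot.center_px[0], cols - spot.center_px[1])
    d_edge = float(d_center.min()) - spot.radius_px
    return max(0.0, d_edge) * mm_per_px


def time_to_contact(
    distances_mm: Sequence[float],
    times_min: Sequence[float],
    threshold_mm: float = 0.0,
) -> tuple[float, bool]:
    """First time the distance drops to the threshold; else censored at the end.

    Returns ``(time_min, censored)`` where ``censored`` is True when contact
    never happened within the recording (the time is then the final time).
    """
    if threshold_mm < 0:
        raise ValueError("threshold must be >= 0")
    d = np.asarray(distances_mm, dtype=float)
    t = np.asarray(times_min, dtype=float)
    if d.shape != t.shape or d.size == 0:
        raise ValueError("distance and time series must be equal-length, non-empty")
    hit = np.nonzero(d <= threshold_mm)[0]
    if hit.size:
        return float(t[hit[0]]), False
    return float(t[-1]), True


@dataclass
class SurvivalCurve:
    """Empirical fraction of replicates not yet in contact at each time."""

    times_min: np.ndarray
    P: np.ndarray
    n_replicates: int
    n_censored: int

    def at(self, t: float) -> float:
        """P evaluated at time t (right-continuous step function)."""
        i = np.searchsorted(self.times_min, t, side="right") - 1
        return float(self.P[max(i, 0)]) if i >= 0 else 1.0


def survival_curve(
    contact_times_min: Iterable[float],
    censored: Iterable[bool],
    horizon_min: float | None = None,
) -> SurvivalCurve:
    """Empirical time-to-contact curve across replicates.

    P(t) is the fraction of replicates whose contact time exceeds t; censored
    replicates count as not-reached through the horizon (the latest recorded
    time by default).  With n replicates, P only takes values k/n.
    """
    times = np.asarray(list(contact_times_min), dtype=float)
    cens = np.asarray(list(censored), dtype=bool)
    if times.size == 0:
        raise ValueError("need at least one replicate")
    if horizon_min is None:
        horizon_min = float(times.max())
    n = times.size
    effective = np.where(cens, np.inf, times)
    grid = np.unique(np.concatenate([[0.0], times[~cens], [horizon_min]]))
    P = np.array([(effective > t).sum() / n for t in grid])
    return SurvivalCurve(grid, P, n_replicates=n, n_censored=int(cens.sum()))
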