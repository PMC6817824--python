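"""End-to-end analysis: frames -> trinarized labels -> metric tables.

``analyze_sequence`` runs the full chain on an image stack: a*b* conversion,
per-frame two-cluster k-means binarization (slime reference color taken from
the known initial disc in frame 0), history-based trinarization, growth-event
accounting, shape indices, and — when a spot layout is given — the distance
to the glucose spot.  ``metrics_table`` computes the same tables directly
from trinarized frames, which is also the route for ground-truth labels from
the synthetic generator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .frames_io import ArenaMask, FrameSequence
from .growth import CoverageSeries, accumulate
from .segmentation import (
    DEFAULT_MIN_BLOB_FRAC,
    TrinarizedFrame,
    kmeans_binarize,
    reference_color,
    to_ab,
    trinarize_sequence,
)
from .shape import shape_metrics
from .spots import SpotLayout, distance_to_spot, time_to_contact

__all__ = ["AnalysisResult", "segment_sequence", "metrics_table", "analyze_sequence"]

#: Default erosion radius for the cluster count, as a fraction of arena radius.
DEFAULT_EROSION_FRAC = 0.02


@dataclass
class AnalysisResult:
    """Everything one replicate produces: labels, the metric table, provenance."""

    frames: list[TrinarizedFrame]
    coverage: CoverageSeries
    params: dict

    @property
    def table(self) -> pd.DataFrame:
        return self.coverage.table

    def run_log(self) -> dict:
        blob = json.dumps(self.params, sort_keys=True, default=str)
        return {
            "package_version": __version__,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "params": self.params,
        }


def segment_sequence(
    seq: FrameSequence,
    arena: ArenaMask,
    initial_slime: tuple[tuple[float, float], float],
    seed: int = 0,
    min_blob_frac: float = DEFAULT_MIN_BLOB_FRAC,
) -> list[TrinarizedFrame]:
    """Binarize every frame by k-means in a*b* and trinarize from pixel history.

    ``initial_slime`` is the (center_px, radius_px) of the plasmodium disc at
    frame 0; its mean a*b* is the slime reference color for cluster
    identification in every frame.
    """
    ab0 = to_ab(seq[0])
    center, radius = initial_slime
    ref = reference_color(ab0, center, radius)
    masks = []
    for t in range(len(seq)):
        ab = ab0 if t == 0 else to_ab(seq[t])
        try:
            masks.append(kmeans_binarize(ab, arena, ref, seed=seed, min_blob_frac=min_blob_frac))
        except ValueError as e:
            raise ValueError(f"segmentation failed at frame {t}: {e}") from e
    return trinarize_sequence(masks, arena)


def metrics_table(
    frames: list[TrinarizedFrame],
    interval_min: float,
    erosion_frac: float = DEFAULT_EROSION_FRAC,
    layout: SpotLayout | None = None,
    pool_window_min: float = 60.0,
) -> CoverageSeries:
    """Coverage/growth table augmented with shape indices and spot distances."""
    cov = accumulate(frames, interval_min, pool_window_min=pool_window_min)
    arena = frames[0].arena
    erosion_mm = erosion_frac * arena.radius_px * arena.mm_per_px

    shp_rows = []
    for f in frames:
        m = f.slime
        if m.any():
            s = shape_metrics(m, arena.mm_per_px, erosion_mm)
            shp_rows.append(dict(circularity=s.C, eccentricity=s.E,
                                 solidity=s.S, n_clusters=s.n_clusters))
        else:
            shp_rows.append(dict(circularity=np.nan, eccentricity=np.nan,
                                 solidity=np.nan, n_clusters=0))
    cov.table = pd.concat([cov.table, pd.DataFrame(shp_rows)], axis=1)

    if layout is not None:
        dists = []
        for f in frames:
            m = f.slime
            dists.append(
                distance_to_spot(m, layout, arena.mm_per_px) if m.any() else np.nan
            )
        cov.table["distance_to_glucose_mm"] = dists
    return cov


def analyze_sequence(
    seq: FrameSequence,
    arena: ArenaMask,
    initial_slime: tuple[tuple[float, float], float],
    seed: int = 0,
    min_blob_frac: float = DEFAULT_MIN_BLOB_FRAC,
    erosion_frac: float = DEFAULT_EROSION_FRAC,
    layout: SpotLayout | None = None,
    pool_window_min: float = 60.0,
) -> AnalysisResult:
    """Full pipeline on one image sequence."""
    if layout is not None:
        layout.validate(arena)
    frames = segment_sequence(seq, arena, initial_slime, seed=seed, min_blob_frac=min_blob_frac)
    cov = metrics_table(frames, seq.interval_min, erosion_frac=erosion_frac,
                        layout=layout, pool_window_min=pool_window_min)
    params = dict(
        n_frames=len(seq), interval_min=seq.interval_min,
        arena_center_px=arena.center_px, arena_radius_px=arena.radius_px,
        mm_per_px=arena.mm_per_px, initial_slime=initial_slime,
        seed=seed, min_blob_frac=min_blob_frac, erosion_frac=erosion_frac,
        has_spots=layout is not None,
    )
    return AnalysisResult(frames, cov, params)


def contact_time_from_table(table: pd.DataFrame, threshold_mm: float = 0.0) -> tuple[float, bool]:
    """Time-to-contact of one replicate from its metric table."""
    if "distance_to_glucose_mm" not in table:
        raise ValueError("table has no distance_to_glucose_mm column")
    return time_to_contact(
        table["distance_to_glucose_mm"].to_numpy(),
        table["time_min"].to_numpy(),
        threshold_mm,
    )
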