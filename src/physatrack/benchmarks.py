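"""Reference experiments on synthetic data.

Self-contained routines that exercise the pipeline end to end under known
conditions: ground-truth recovery of the segmentation, migration-rate
parameter recovery on constant-velocity growth, and the observed-vs-expected
secondary-growth calibration.  They back both the test suite and the
reproduction script, so the problem sizes here are the package's reference
benchmark sizes.
"""

from __future__ import annotations

import numpy as np

from .growth import (
    classify_transitions,
    expansion_region,
    growth_extents,
    migration_rate,
    secondary_growth_bias,
)
from .pipeline import analyze_sequence
from .synth import SynthParams, generate

__all__ = [
    "groundtruth_recovery",
    "migration_recovery",
    "bias_experiment",
    "null_bias_params",
]


def _initial_disc(params: SynthParams):
    return params.slime_center_px(), params.slime_diameter_mm / 2.0 / params.mm_per_px


def groundtruth_recovery(
    noise_sigma: float,
    seed: int = 0,
    n_frames: int = 30,
    image_size: int = 192,
) -> float:
    """Minimum per-frame pixelwise agreement between pipeline labels and truth.

    Renders a control-like run at the given color-noise level, re-analyzes the
    rendered frames blind, and compares every trinarized frame to the
    generator's ground truth over the arena.  Returns the worst frame's
    agreement (1.0 = perfect).
    """
    params = SynthParams(
        duration_min=n_frames * 5.0, image_size=image_size,
        growth_rate_mm_min=0.3, retraction_prob=0.3, retract_radius_mm=8.0,
        pseudopod_rate=1.0, noise_sigma=noise_sigma, seed=seed,
    )
    seq, truth, _ = generate(params)
    arena = truth[0].arena
    result = analyze_sequence(seq, arena, _initial_disc(params))
    agree = [
        (result.frames[i].labels[arena.mask] == truth[i].labels[arena.mask]).mean()
        for i in range(len(truth))
    ]
    return float(min(agree))


def migration_recovery(
    v_mm_min: float, seed: int = 1, n_frames: int = 10, image_size: int = 320
) -> tuple[np.ndarray, float]:
    """Pipeline-measured migration rates for uniform outward growth at speed v.

    Deterministic radial growth (every candidate pixel grows, no withdrawal,
    no lobes), noise-free render, full segmentation pipeline.  Returns the
    per-interval rates and the one-pixel-per-interval tolerance in mm/min.
    """
    params = SynthParams(
        duration_min=n_frames * 5.0, image_size=image_size,
        growth_rate_mm_min=v_mm_min, grow_fraction=1.0,
        retraction_prob=0.0, pseudopod_rate=0.0, noise_sigma=0.0, seed=seed,
    )
    seq, truth, _ = generate(params)
    result = analyze_sequence(seq, truth[0].arena, _initial_disc(params))
    rates = result.table["migration_rate_mm_min"].iloc[1:].to_numpy()
    tol = params.mm_per_px / params.interval_min
    return rates, tol


def null_bias_params(mucus_bias: float, seed: int, n_steps: int = 90,
                     image_size: int = 128) -> SynthParams:
    """Generator configuration for the secondary-growth calibration runs.

    Growth placement is the only stochastic spatial mechanism: no pseudopod
    lobes, no chemoattraction, and no sub-resolution engulfment (which is a
    deterministic sheet-continuity rule that preferentially converts enclosed
    mucus and would confound the placement null).  Frequent frontier
    withdrawal keeps mucus present in the expansion region.
    """
    return SynthParams(
        duration_min=n_steps * 5.0, image_size=image_size,
        growth_rate_mm_min=0.3, grow_fraction=0.45,
        retraction_prob=0.5, retract_radius_mm=10.0,
        pseudopod_rate=0.0, mucus_bias=mucus_bias,
        noise_sigma=0.0, speckle_px=0, seed=seed,
    )


def bias_experiment(
    mucus_bias: float,
    seeds: tuple[int, ...] = (11, 12, 13),
    n_steps: int = 90,
    image_size: int = 128,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and expected secondary-growth fractions over valid intervals.

    Pools ground-truth-label runs across seeds; an interval is valid when
    growth occurred and its expansion region contains both mucus and
    unexplored substrate (otherwise the comparison is degenerate).
    """
    obs_all, exp_all = [], []
    for seed in seeds:
        params = null_bias_params(mucus_bias, seed, n_steps, image_size)
        _, truth, _ = generate(params, render=False)
        arena = truth[0].arena
        for t in range(1, len(truth)):
            prev, curr = truth[t - 1], truth[t]
            if not prev.slime.any():
                continue
            tm = classify_transitions(prev, curr)
            ext = growth_extents(tm, prev.slime, arena.mm_per_px)
            rate = migration_rate(ext, params.interval_min)
            region = expansion_region(prev, rate * params.interval_min)
            obs, exp = secondary_growth_bias(tm, region, prev)
            if np.isnan(obs) or np.isnan(exp):
                continue
            if not ((region & prev.mucus).any() and (region & prev.unexplored).any()):
                continue
            obs_all.append(obs)
            exp_all.append(exp)
    return np.asarray(obs_all), np.asarray(exp_all)
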