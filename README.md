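# physatrack

Automated time-lapse image analysis of *Physarum polycephalum* exploration.

A plasmodium placed in a circular petri-dish arena explores its surroundings
by extending pseudopods and withdrawing again, leaving a trace of
extracellular mucus on every patch it abandons. `physatrack` turns an
ordered stack of arena photographs (typically one frame every 5 minutes for
35 hours) into quantitative exploration metrics:

- **Trinarized segmentation.** Each frame is reduced to the a\*b\*
  chromaticity plane (CIELAB without the lightness channel) and split into
  slime / not-slime by two-cluster k-means over the in-arena pixels; pixel
  history then refines not-slime into *mucus* (ever visited) or *unexplored
  substrate* (never visited). A visited pixel can never return to the
  unexplored state.
- **Growth events.** Between consecutive frames every pixel undergoes at
  most one event: *primary growth* (unexplored → slime), *secondary growth*
  (mucus → slime, a revisit), or *refinement* (slime → mucus, a withdrawal),
  with the exact per-interval balance
  Δslime = primary + secondary − refinement.
- **Migration rate.** The maximum distance from any grown pixel to the
  previous slime set (exact Euclidean distance transform), divided by the
  sampling interval, in mm/min. The band of non-slime pixels within that
  distance of the previous contour is the *expansion region*, and the
  observed vs expected secondary-growth fractions over it measure whether
  the organism prefers previously explored substrate — its mucus acting as
  a buffer in adverse environments.
- **Morphometry.** Per frame: circularity C = P²/(4πA), eccentricity
  E = √(1 − (b/a)²) of the moment-equivalent ellipse, solidity (area over
  convex-hull area), and the pseudopod count as connected components
  surviving a disc erosion.
- **Spot experiments.** Minimum distance from the slime contour to a
  glucose spot and the empirical survival-style curve P(t) — the fraction
  of replicates that have not reached the spot by time t.
- **Synthetic benchmark.** A lattice simulation with known ground truth
  (frontier growth, pseudopod lobes, withdrawal, substrate preference,
  chemoattraction, noisy three-color rendering) so every stage is testable
  without original photographs.

## Worked example

Generate a five-hour synthetic control recording and analyze it blind:

```python
from physatrack import SynthParams, generate, analyze_sequence

params = SynthParams(duration_min=300, image_size=192, seed=42)
seq, truth, log = generate(params)
arena = truth[0].arena
result = analyze_sequence(
    seq, arena,
    initial_slime=(params.slime_center_px(),
                   params.slime_diameter_mm / 2 / params.mm_per_px),
)
cols = ["time_min", "frac_slime", "frac_mucus", "migration_rate_mm_min",
        "cum_secondary", "circularity", "solidity", "n_clusters"]
print(result.table[cols].iloc[::12].round(3).to_string(index=False))
```

```
 time_min  frac_slime  frac_mucus  migration_rate_mm_min  cum_secondary  circularity  solidity  n_clusters
      0.0       0.030       0.000                    NaN          0.000        1.029     0.969           1
     60.0       0.079       0.000                  0.161          0.008        1.557     0.919           1
    120.0       0.103       0.017                  0.161          0.017        2.840     0.805           1
    180.0       0.164       0.009                  0.228          0.043        3.275     0.830           1
    240.0       0.231       0.014                  0.161          0.059        3.564     0.832           1
```

The initial 2.5 cm disc (3% of the 14.5 cm arena, circularity ≈ 1,
solidity ≈ 1) spreads to 23% coverage within four hours; mucus appears once
the first withdrawals begin, cumulative secondary growth accumulates as the
cell revisits its own trace, and circularity rises as the contour departs
from a circle. The migration rate hovers around the generator's frontier
speed of 0.2 mm/min (quantized by the 0.42 mm pixel pitch).

The same pipeline runs from the shell:

```sh
physatrack synth --preset adverse --out run1 --seed 7
physatrack analyze --config config.yaml      # arena geometry, knobs, paths
physatrack report run*/metrics.csv --out summary --plot
```

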