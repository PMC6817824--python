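"""Synthetic slime-mold time-lapse generator with known ground truth.

A lattice simulation emulates the experiments' geometry and dynamics: a
circular plasmodium disc (2.5 cm) in the center of a circular arena
(14.5 cm), photographed every 5 minutes for 35 hours (420 frames).  Each
step the growth frontier advances by up to ``growth_rate_mm_min`` into a
ring of candidate pixels; candidates are occupied stochastically with
weights shaped by transient directional lobes (pseudopods), by optional
chemoattraction toward a glucose spot, and by ``mucus_bias`` — the
preference for regrowing onto previously explored (mucus-covered) substrate
over virgin substrate, the signature of exploration in adverse environments.
Withdrawal events carve a disc out of the plasmodium near its frontier,
leaving mucus behind.

Detached slime fragments and enclosed substrate pockets below the speckle
scale (a few pixels) are absorbed at each step: the plasmodium is a
continuous sheet and structures below the imaging resolution are not
meaningful.  Frames are rendered as per-class mean colors plus i.i.d.
Gaussian noise, with a fixed dark color outside the arena.

Randomness: one generator seeded from ``seed`` drives the dynamics, drawing
in a fixed order per step (withdrawal, lobe births, growth selection);
rendering noise uses an independent per-frame stream derived from the same
seed, so identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .frames_io import ArenaMask, FrameSequence, make_arena
from .labels import Label
from .segmentation import TrinarizedFrame
from .spots import Spot, SpotLayout

__all__ = ["SynthParams", "generate", "render_frame", "PRESETS", "preset"]


@dataclass
class SynthParams:
    """Full parameterization of the synthetic time-lapse generator.

    Geometry defaults mirror the experimental setup: 14.5 cm arena, 2.5 cm
    initial plasmodium, 5-min sampling for 35 h (420 frames).  Dynamics
    defaults describe a neutral (control-like) substrate: frontier speed
    0.2 mm/min (1.2 cm/h, mid-range for a plasmodium), about one new
    pseudopod lobe per hour, occasional withdrawal, and no substrate
    preference (``mucus_bias = 1``).
    """

    # geometry / timing
    arena_diameter_mm: float = 145.0
    slime_diameter_mm: float = 25.0
    interval_min: float = 5.0
    duration_min: float = 2100.0
    image_size: int = 256
    arena_margin_px: int = 6

    # dynamics
    growth_rate_mm_min: float = 0.2
    grow_fraction: float = 0.7
    pseudopod_rate: float = 1.0           # expected new lobes per hour
    lobe_lifetime_min: float = 60.0
    lobe_gain: float = 2.0
    lobe_width_rad: float = 0.5
    retraction_prob: float = 0.25         # per step
    retract_radius_mm: float = 8.0
    max_slime_frac: float = 0.35          # biomass cap: withdrawal pressure above it
    mucus_bias: float = 1.0               # >1: prefers regrowth onto mucus
    start_delay_min: float = 0.0

    # spot experiment (optional)
    glucose_spot: bool = False
    salt_spot: bool = False
    spot_diameter_mm: float = 25.0
    spot_distance_mm: float = 45.0
    spot_distance_mode: str = "edge"      # "edge" or "center" separation
    chemoattraction: float = 0.0          # directional weight toward glucose

    # rendering
    slime_rgb: tuple[int, int, int] = (210, 175, 40)
    mucus_rgb: tuple[int, int, int] = (200, 160, 170)
    substrate_rgb: tuple[int, int, int] = (150, 160, 185)
    outside_rgb: tuple[int, int, int] = (40, 40, 45)
    noise_sigma: float = 5.0

    speckle_px: int | None = None         # auto: max(4, 1e-4 * arena area)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.retraction_prob <= 1.0):
            raise ValueError("retraction_prob must be in [0, 1]")
        if not (0.0 < self.grow_fraction <= 1.0):
            raise ValueError("grow_fraction must be in (0, 1]")
        for name in ("growth_rate_mm_min", "pseudopod_rate", "mucus_bias",
                     "noise_sigma", "start_delay_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.interval_min <= 0 or self.duration_min <= 0:
            raise ValueError("interval_min and duration_min must be > 0")
        if self.spot_distance_mode not in ("edge", "center"):
            raise ValueError("spot_distance_mode must be 'edge' or 'center'")
        if self.slime_diameter_mm >= self.arena_diameter_mm:
            raise ValueError("slime disc must fit inside the arena")

    # ---- derived geometry -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(round(self.duration_min / self.interval_min))

    @property
    def arena_radius_px(self) -> float:
        return self.image_size // 2 - self.arena_margin_px

    @property
    def arena_center_px(self) -> tuple[float, float]:
        c = (self.image_size - 1) / 2.0
        return (c, c)

    @property
    def mm_per_px(self) -> float:
        return self.arena_diameter_mm / (2.0 * self.arena_radius_px)

    def make_arena(self) -> ArenaMask:
        return make_arena(
            self.arena_center_px,
            self.arena_radius_px,
            self.arena_diameter_mm,
            (self.image_size, self.image_size),
        )

    def _spot_separation_px(self) -> float:
        sep_mm = self.spot_distance_mm
        if self.spot_distance_mode == "edge":
            sep_mm += (self.slime_diameter_mm + self.spot_diameter_mm) / 2.0
        return sep_mm / self.mm_per_px

    def slime_center_px(self) -> tuple[float, float]:
        cr, cc = self.arena_center_px
        if self.glucose_spot:
            return (cr, cc - self._spot_separation_px() / 2.0)
        return (cr, cc)

    def make_layout(self) -> SpotLayout | None:
        """Spot layout implied by the parameters (None without spots)."""
        if not self.glucose_spot:
            return None
        cr, cc = self.arena_center_px
        sep = self._spot_separation_px()
        r_spot = self.spot_diameter_mm / 2.0 / self.mm_per_px
        spots = [
            Spot((cr, cc - sep / 2.0), self.slime_diameter_mm / 2.0 / self.mm_per_px, "origin"),
            Spot((cr, cc + sep / 2.0), r_spot, "glucose"),
        ]
        if self.salt_spot:
            spots.append(Spot((cr, cc), r_spot, "salt"))
        return SpotLayout(spots)

    @property
    def effective_speckle_px(self) -> int:
        if self.speckle_px is not None:
            return self.speckle_px
        arena_area = np.pi * self.arena_radius_px**2
        return max(4, int(round(1e-4 * arena_area)))


#: Parameter bundles reproducing the qualitative treatment orderings
#: (illustrative, not fitted to any measured curve).
PRESETS: dict[str, dict] = {
    "control": {},
    "nutritive": dict(growth_rate_mm_min=0.15, pseudopod_rate=0.7,
                      retraction_prob=0.15),
    "highly_nutritive": dict(growth_rate_mm_min=0.08, pseudopod_rate=0.4,
                             retraction_prob=0.08, start_delay_min=120.0),
    "adverse": dict(start_delay_min=180.0, mucus_bias=5.0, retraction_prob=0.45,
                    pseudopod_rate=0.6, grow_fraction=0.5),
    "spot_experiment": dict(glucose_spot=True, chemoattraction=1.0,
                            pseudopod_rate=0.5, retraction_prob=0.1),
}


def preset(name: str, **overrides) -> SynthParams:
    """A named parameter bundle, with optional field overrides."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SynthParams(**kwargs)


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


def _absorb_speckle(slime: np.ndarray, speckle_px: int) -> np.ndarray:
    """Drop detached fragments and close enclosed pockets at or below the speckle scale."""
    lab, n = ndimage.label(slime, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = np.bincount(lab.ravel())
        keep = sizes > speckle_px
        keep[0] = False
        # always keep the largest component, whatever its size
        keep[1 + np.argmax(sizes[1:])] = True
        slime = keep[lab]
    filled = ndimage.binary_fill_holes(slime)
    pockets = filled & ~slime
    if pockets.any():
        plab, pn = ndimage.label(pockets, structure=np.ones((3, 3), dtype=int))
        psizes = np.bincount(plab.ravel())
        small = psizes <= speckle_px
        small[0] = False
        slime = slime | small[plab]
    return slime


def render_frame(
    labels: np.ndarray,
    params: SynthParams,
    rng: np.random.Generator,
    arena_mask: np.ndarray,
) -> np.ndarray:
    """Render a ground-truth label grid as a noisy RGB photograph.

    Per-class mean color plus i.i.d. Gaussian noise clipped to [0, 255];
    outside-arena pixels take a fixed dark color.
    """
    colors = {
        int(Label.UNEXPLORED): params.substrate_rgb,
        int(Label.SLIME): params.slime_rgb,
        int(Label.MUCUS): params.mucus_rgb,
    }
    lut = np.zeros((3, 3), dtype=float)
    for code, rgb in colors.items():
        lut[code] = rgb
    img = lut[labels]
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
    img[~arena_mask] = params.outside_rgb
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate(
    params: SynthParams, render: bool = True
) -> tuple[FrameSequence | None, list[TrinarizedFrame], pd.DataFrame]:
    """Run the lattice simulation and (optionally) render it.

    Returns the rendered :class:`FrameSequence` (or None when ``render`` is
    False), the ground-truth trinarized frames, and a per-step log of the
    true dynamics (growth-event pixel counts, true maximum growth extent,
    active lobes, withdrawal flags).
    """
    arena = params.make_arena()
    step_px = params.growth_rate_mm_min * params.interval_min / params.mm_per_px
    slime_r_px = params.slime_diameter_mm / 2.0 / params.mm_per_px
    if slime_r_px + step_px > params.arena_radius_px:
        raise ValueError(
            "growth rate so large the slime mold would exit the arena in one step"
        )

    slime = _disc_mask(arena.mask.shape, params.slime_center_px(), slime_r_px) & arena.mask
    if not slime.any():
        raise ValueError("initial slime disc is empty at this resolution")
    ever = slime.copy()
    speckle = params.effective_speckle_px
    retract_r_px = max(1.0, params.retract_radius_mm / params.mm_per_px)

    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    lobes: list[tuple[float, int]] = []  # (angle, expiry step)
    lobe_steps = max(1, int(round(params.lobe_lifetime_min / params.interval_min)))
    # Fractional-advance carry: when the nominal per-step advance is below the
    # pixel pitch the un-realized distance accrues, so the front moves at the
    # nominal speed at any resolution.  Capped so a stalled front cannot burst.
    residual = 0.0
    residual_cap = step_px + 1.5

    layout = params.make_layout()
    spot_center = layout.glucose.center_px if layout is not None else None

    def make_labels(s: np.ndarray, e: np.ndarray) -> np.ndarray:
        lab = np.zeros(arena.mask.shape, dtype=np.uint8)
        lab[s] = Label.SLIME
        lab[~s & e & arena.mask] = Label.MUCUS
        return lab

    label_grids = [make_labels(slime, ever)]
    log_rows = [dict(time_min=0.0, n_primary=0, n_secondary=0, n_refinement=0,
                     true_max_extent_mm=0.0, true_migration_rate_mm_min=0.0,
                     n_lobes=0, retracted=False)]

    for t in range(1, params.n_frames):
        slime_prev = slime.copy()
        retracted = False
        if t * params.interval_min > params.start_delay_min:
            # 1) withdrawal: carve a disc around a random frontier pixel.
            # The plasmodium has finite biomass: above max_slime_frac the
            # sheet is overstretched and withdrawal is forced, which keeps
            # slime coverage bounded and sustains refinement/regrowth cycles.
            if params.retraction_prob > 0:
                stochastic_carve = rng.random() < params.retraction_prob
                carve_area = np.pi * retract_r_px**2
                cap_px = params.max_slime_frac * arena.n_px
                # enough carves to work off the overstretch, bounded per step
                n_forced = int(np.ceil(max(0.0, slime.sum() - cap_px) / carve_area))
                for k in range(min(8, max(n_forced, 1))):
                    overstretched = slime.sum() > cap_px
                    if not (overstretched or (k == 0 and stochastic_carve)):
                        break
                    frontier = slime & ~ndimage.binary_erosion(slime)
                    fr, fc = np.nonzero(frontier)
                    if not fr.size:
                        break
                    i = rng.integers(fr.size)
                    carve = _disc_mask(slime.shape, (fr[i], fc[i]), retract_r_px)
                    remaining = slime & ~carve
                    if remaining.any():
                        remaining = _absorb_speckle(remaining, speckle)
                    if not remaining.any():
                        break
                    slime = remaining
                    retracted = True

            # 2) pseudopod lobes
            n_new = rng.poisson(params.pseudopod_rate * params.interval_min / 60.0)
            for _ in range(n_new):
                lobes.append((rng.uniform(0.0, 2.0 * np.pi), t + lobe_steps))
            lobes = [(a, exp) for a, exp in lobes if exp > t]

            # 3) frontier growth into the candidate ring
            eff_step = min(step_px + residual, residual_cap)
            dist = ndimage.distance_transform_edt(~slime)
            cand = arena.mask & ~slime & (dist > 0) & (dist <= eff_step)
            cr_idx, cc_idx = np.nonzero(cand)
            achieved = 0.0
            if cr_idx.size:
                w = np.ones(cr_idx.size)
                if params.mucus_bias != 1.0:
                    on_mucus = ever[cr_idx, cc_idx]
                    w[on_mucus] *= params.mucus_bias
                if lobes or (spot_center is not None and params.chemoattraction > 0):
                    com = ndimage.center_of_mass(slime)
                    theta = np.arctan2(cr_idx - com[0], cc_idx - com[1])
                    for a, _ in lobes:
                        delta = np.angle(np.exp(1j * (theta - a)))
                        w *= 1.0 + params.lobe_gain * np.exp(
                            -0.5 * (delta / params.lobe_width_rad) ** 2
                        )
                    if spot_center is not None and params.chemoattraction > 0:
                        phi = np.arctan2(spot_center[0] - com[0], spot_center[1] - com[1])
                        w *= np.exp(params.chemoattraction * np.cos(theta - phi))
                p = np.minimum(1.0, params.grow_fraction * w / w.max())
                grown = rng.random(cr_idx.size) < p
                if grown.any():
                    achieved = float(dist[cr_idx[grown], cc_idx[grown]].max())
                slime[cr_idx[grown], cc_idx[grown]] = True
                slime = _absorb_speckle(slime, speckle)
            residual = min(eff_step - achieved, residual_cap)

        new_px = slime & ~slime_prev
        if new_px.any():
            d_prev = ndimage.distance_transform_edt(~slime_prev)
            ext_mm = float(d_prev[new_px].max()) * params.mm_per_px
        else:
            ext_mm = 0.0
        n_pri = int((new_px & ~ever).sum())
        n_sec = int((new_px & ever).sum())
        n_ref = int((slime_prev & ~slime).sum())
        ever |= slime
        label_grids.append(make_labels(slime, ever))
        log_rows.append(dict(
            time_min=t * params.interval_min,
            n_primary=n_pri, n_secondary=n_sec, n_refinement=n_ref,
            true_max_extent_mm=ext_mm,
            true_migration_rate_mm_min=ext_mm / params.interval_min,
            n_lobes=len(lobes), retracted=retracted,
        ))

    truth = [TrinarizedFrame(g, i, arena) for i, g in enumerate(label_grids)]
    log = pd.DataFrame(log_rows)

    seq = None
    if render:
        frames = np.empty((params.n_frames, params.image_size, params.image_size, 3),
                          dtype=np.uint8)
        for i, g in enumerate(label_grids):
            frng = np.random.default_rng(
                np.random.SeedSequence(entropy=params.seed, spawn_key=(1, i))
            )
            frames[i] = render_frame(g, params, frng, arena.mask)
        seq = FrameSequence(frames, params.interval_min)
    return seq, truth, log
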