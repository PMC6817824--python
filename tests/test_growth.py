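import numpy as np
import pytest

from physatrack import (
    accumulate,
    classify_transitions,
    coverage_fractions,
    expansion_region,
    growth_extents,
    migration_rate,
    secondary_growth_bias,
    trinarize_sequence,
)
from physatrack.labels import Event, Label

from conftest import disc_mask, trin_frame


class TestClassifyTransitions:
    @pytest.mark.parametrize(
        "prev_lab, curr_lab, expected",
        [
            (Label.UNEXPLORED, Label.SLIME, Event.PRIMARY),
            (Label.MUCUS, Label.SLIME, Event.SECONDARY),
            (Label.SLIME, Label.MUCUS, Event.REFINEMENT),
            (Label.UNEXPLORED, Label.UNEXPLORED, Event.NONE),
            (Label.SLIME, Label.SLIME, Event.NONE),
            (Label.MUCUS, Label.MUCUS, Event.NONE),
        ],
    )
    def test_event_table(self, small_arena, prev_lab, curr_lab, expected):
        pix = (31, 31)
        prev = trin_frame(small_arena, index=0)
        curr = trin_frame(small_arena, index=1)
        prev.labels[pix] = prev_lab
        curr.labels[pix] = curr_lab
        tm = classify_transitions(prev, curr)
        assert Event(tm.events[pix]) == expected

    def test_nonconsecutive_frames_rejected(self, small_arena):
        with pytest.raises(ValueError, match="consecutive"):
            classify_transitions(trin_frame(small_arena, index=0),
                                 trin_frame(small_arena, index=2))


class TestCoverage:
    def test_all_slime(self, small_arena):
        f = trin_frame(small_arena, slime=np.ones_like(small_arena.mask))
        assert coverage_fractions(f) == (1.0, 0.0, 0.0)

    def test_fractions_sum_to_one(self, small_arena):
        rng = np.random.default_rng(1)
        f = trin_frame(small_arena,
                       slime=rng.random(small_arena.mask.shape) < 0.3,
                       mucus=rng.random(small_arena.mask.shape) < 0.5)
        assert sum(coverage_fractions(f)) == pytest.approx(1.0, abs=1e-9)


def _brute_force_extents(growth_mask, prev_slime):
    """O(n^2) nearest-neighbour oracle for growth distances."""
    gs = np.argwhere(growth_mask)
    ss = np.argwhere(prev_slime)
    return np.array([np.sqrt(((g - ss) ** 2).sum(axis=1)).min() for g in gs])


class TestGrowthExtents:
    def test_adjacent_pixel_distance_one(self, small_arena):
        prev = trin_frame(small_arena, slime=disc_mask((64, 64), (31, 31), 3))
        curr_slime = disc_mask((64, 64), (31, 31), 3).copy()
        curr_slime[31, 35] = True  # 4-neighbour of the rim pixel (31, 34)
        curr = trin_frame(small_arena, slime=curr_slime, index=1)
        tm = classify_transitions(prev, curr)
        ext = growth_extents(tm, prev.slime, small_arena.mm_per_px)
        assert ext == pytest.approx([1.0])

    def test_annulus_against_bruteforce(self, small_arena):
        inner = disc_mask((64, 64), (31.5, 31.5), 8)
        outer = disc_mask((64, 64), (31.5, 31.5), 11)
        prev = trin_frame(small_arena, slime=inner)
        curr = trin_frame(small_arena, slime=outer, index=1)
        tm = classify_transitions(prev, curr)
        ext = np.sort(growth_extents(tm, prev.slime, small_arena.mm_per_px))
        oracle = np.sort(_brute_force_extents(tm.growth, prev.slime & small_arena.mask))
        assert np.allclose(ext, oracle)
        # max extent equals the annulus width within half a pixel
        assert ext.max() == pytest.approx(3.0, abs=0.5)

    def test_empty_previous_slime_errors(self, small_arena):
        prev = trin_frame(small_arena)
        curr = trin_frame(small_arena, slime=disc_mask((64, 64), (31, 31), 3), index=1)
        tm = classify_transitions(prev, curr)
        with pytest.raises(ValueError, match="empty"):
            growth_extents(tm, prev.slime, 1.0)


class TestMigrationRate:
    def test_ratio_definition(self):
        assert migration_rate(np.array([0.4, 1.0]), 5.0) == pytest.approx(0.2)

    def test_no_growth_is_zero(self):
        assert migration_rate(np.array([]), 5.0) == 0.0


class TestExpansionRegion:
    def test_zero_offset_empty(self, small_arena):
        prev = trin_frame(small_arena, slime=disc_mask((64, 64), (31.5, 31.5), 10))
        assert not expansion_region(prev, 0.0).any()

    def test_annulus_area_analytic(self):
        # radii large enough that the sub-pixel band-edge bias is below 2%
        from physatrack import make_arena
        n, r, k = 200, 40, 25
        arena = make_arena(((n - 1) / 2, (n - 1) / 2), n // 2 - 4, float(n - 8), (n, n))
        prev = trin_frame(arena, slime=disc_mask((n, n), ((n - 1) / 2, (n - 1) / 2), r))
        region = expansion_region(prev, float(k))  # mm_per_px = 1
        analytic = np.pi * ((r + k) ** 2 - r**2)
        assert region.sum() == pytest.approx(analytic, rel=0.02)

    def test_saturates_to_all_nonslime(self, small_arena):
        slime = disc_mask((64, 64), (31.5, 31.5), 5)
        prev = trin_frame(small_arena, slime=slime)
        region = expansion_region(prev, 1000.0)
        assert np.array_equal(region, small_arena.mask & ~prev.slime)


class TestSecondaryBias:
    def test_observed_fraction_definition(self, small_arena):
        prev = trin_frame(small_arena)
        ev = np.zeros((64, 64), np.uint8)
        ev.flat[:30] = Event.SECONDARY
        ev.flat[30:50] = Event.PRIMARY
        from physatrack.growth import TransitionMap
        tm = TransitionMap(ev, 1, small_arena)
        obs, _ = secondary_growth_bias(tm, np.zeros((64, 64), bool), prev)
        assert obs == pytest.approx(0.6)

    def test_expected_fraction_definition(self, small_arena):
        mucus = np.zeros((64, 64), bool)
        mucus[20:26, 20:30] = True  # 60 px of mucus
        region = np.zeros((64, 64), bool)
        region[20:30, 20:30] = True  # 100 px region, 60 mucus / 40 unexplored
        prev = trin_frame(small_arena, mucus=mucus)
        from physatrack.growth import TransitionMap
        tm = TransitionMap(np.zeros((64, 64), np.uint8), 1, small_arena)
        _, exp = secondary_growth_bias(tm, region, prev)
        assert exp == pytest.approx(0.6)

    def test_degenerate_interval_is_nan(self, small_arena):
        from physatrack.growth import TransitionMap
        tm = TransitionMap(np.zeros((64, 64), np.uint8), 1, small_arena)
        obs, exp = secondary_growth_bias(tm, np.zeros((64, 64), bool), trin_frame(small_arena))
        assert np.isnan(obs) and np.isnan(exp)

    def test_uniform_random_growth_is_unbiased(self, small_arena):
        """Monte-Carlo: growth placed uniformly in the region -> observed ~ expected."""
        rng = np.random.default_rng(7)
        slime = disc_mask((64, 64), (31.5, 31.5), 10)
        mucus = np.zeros((64, 64), bool)
        mucus[:, :32] = True  # half-plane previously explored
        mucus &= ~slime
        prev = trin_frame(small_arena, slime=slime, mucus=mucus)
        region = expansion_region(prev, 4.0)
        region_idx = np.argwhere(region)
        obs_list, exp_ref = [], None
        for _ in range(300):
            pick = region_idx[rng.choice(len(region_idx), size=30, replace=False)]
            curr_slime = slime.copy()
            curr_slime[pick[:, 0], pick[:, 1]] = True
            curr = trin_frame(small_arena, slime=curr_slime,
                              mucus=mucus & ~curr_slime, index=1)
            tm = classify_transitions(prev, curr)
            obs, exp = secondary_growth_bias(tm, region, prev)
            obs_list.append(obs)
            exp_ref = exp
        obs_arr = np.array(obs_list)
        se = obs_arr.std(ddof=1) / np.sqrt(len(obs_arr))
        assert abs(obs_arr.mean() - exp_ref) < 3 * se


class TestAccumulate:
    def _frames(self, small_arena, seed=3, n=8):
        rng = np.random.default_rng(seed)
        masks = [disc_mask((64, 64), (31.5, 31.5), 6)]
        for _ in range(n - 1):
            m = masks[-1].copy()
            grow = rng.random(m.shape) < 0.08
            shrink = rng.random(m.shape) < 0.04
            masks.append((m | grow) & ~shrink | disc_mask((64, 64), (31.5, 31.5), 2))
        return trinarize_sequence(masks, small_arena)

    def test_area_balance_identity(self, small_arena):
        cov = accumulate(self._frames(small_arena), interval_min=5.0)
        df = cov.table
        ds = df["frac_slime"].diff().iloc[1:]
        bal = (df["primary"] + df["secondary"] - df["refinement"]).iloc[1:]
        assert np.allclose(ds, bal, atol=1e-12)

    def test_cumulative_primary_equals_explored(self, small_arena):
        cov = accumulate(self._frames(small_arena), interval_min=5.0)
        df = cov.table
        explored = df["frac_slime"] + df["frac_mucus"]
        assert np.allclose(df["cum_primary"], explored, atol=1e-12)
        assert df["cum_primary"].iloc[-1] <= 1.0

    def test_cumulative_series_non_decreasing(self, small_arena):
        df = accumulate(self._frames(small_arena), interval_min=5.0).table
        for c in ("cum_primary", "cum_secondary", "cum_refinement"):
            assert (df[c].diff().iloc[1:] >= -1e-12).all()

    def test_gap_in_indices_rejected(self, small_arena):
        frames = self._frames(small_arena)
        frames[2].frame_index = 7
        with pytest.raises(ValueError, match="gap"):
            accumulate(frames, interval_min=5.0)
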