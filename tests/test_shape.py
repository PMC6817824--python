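import numpy as np
import pytest
from skimage.transform import rotate

from physatrack import circularity, cluster_count, eccentricity, shape_metrics, solidity

from conftest import disc_mask


def _square(side, pad=10):
    m = np.zeros((side + 2 * pad, side + 2 * pad), bool)
    m[pad : pad + side, pad : pad + side] = True
    return m


def _ellipse(a, b, pad=10):
    n = 2 * a + 2 * pad
    rows, cols = np.ogrid[:n, :n]
    c = (n - 1) / 2
    return ((rows - c) / b) ** 2 + ((cols - c) / a) ** 2 <= 1


def _two_discs(r=40):
    n = 4 * r + 40
    m = disc_mask((n, n), (n // 2, r + 10), r) | disc_mask((n, n), (n // 2, 3 * r + 30), r)
    return m


def _plus(arm=40):
    n = 3 * arm + 10
    m = np.zeros((n, n), bool)
    m[5 : 5 + 3 * arm, 5 + arm : 5 + 2 * arm] = True
    m[5 + arm : 5 + 2 * arm, 5 : 5 + 3 * arm] = True
    return m


class TestClosedForms:
    def test_disc_circularity_one(self):
        m = disc_mask((221, 221), (110, 110), 100)
        assert circularity(m) == pytest.approx(1.0, rel=0.02)

    def test_square_circularity(self):
        assert circularity(_square(100)) == pytest.approx(4 / np.pi, rel=0.02)

    def test_two_equal_discs_circularity_two(self):
        assert circularity(_two_discs(60)) == pytest.approx(2.0, rel=0.03)

    def test_disc_eccentricity_zero(self):
        m = disc_mask((181, 181), (90, 90), 80)
        E, a, b = eccentricity(m)
        assert E == pytest.approx(0.0, abs=0.02)
        assert a == pytest.approx(b, rel=0.02)

    def test_ellipse_eccentricity_a_twice_b(self):
        E, a, b = eccentricity(_ellipse(120, 60))
        assert E == pytest.approx(np.sqrt(3) / 2, abs=0.02)
        assert a == pytest.approx(2 * b, rel=0.02)

    def test_single_pixel_eccentricity_zero_by_convention(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        assert eccentricity(m)[0] == 0.0

    def test_disc_solidity_one(self):
        assert solidity(disc_mask((181, 181), (90, 90), 80)) == pytest.approx(1.0, rel=0.02)

    def test_plus_sign_solidity_five_sevenths(self):
        # convex hull of the plus is the bounding octagon, area 7 arm^2
        assert solidity(_plus(60)) == pytest.approx(5 / 7, rel=0.03)

    def test_separated_discs_low_solidity(self):
        s1 = solidity(_two_discs(20))
        n = 300
        far = disc_mask((n, n), (150, 30), 20) | disc_mask((n, n), (150, 270), 20)
        assert solidity(far) < s1 < 1.0


class TestInvariances:
    def test_quarter_turn_exact(self):
        rng = np.random.default_rng(2)
        m = np.zeros((80, 80), bool)
        for _ in range(5):
            r, c = rng.integers(20, 60, 2)
            m |= disc_mask((80, 80), (r, c), rng.integers(4, 10))
        for rot in (1, 2, 3):
            mr = np.rot90(m, rot)
            assert eccentricity(mr)[0] == pytest.approx(eccentricity(m)[0], abs=1e-6)
            assert solidity(mr) == pytest.approx(solidity(m), abs=1e-9)

    def test_arbitrary_rotation_within_two_percent(self):
        m = _ellipse(100, 50)
        mr = rotate(m.astype(float), 33, resize=True, order=0) > 0.5
        assert eccentricity(mr)[0] == pytest.approx(eccentricity(m)[0], abs=0.02)
        assert solidity(mr) == pytest.approx(solidity(m), rel=0.02)

    def test_isoperimetric_lower_bound(self):
        """C >= 1 - eps for random blob unions (discretization allowance 2%)."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = np.zeros((120, 120), bool)
            for _ in range(rng.integers(1, 6)):
                r, c = rng.integers(25, 95, 2)
                m |= disc_mask((120, 120), (r, c), rng.integers(5, 20))
            assert circularity(m) >= 0.98


def _brute_erosion(mask, radius):
    """Naive erosion oracle: keep pixels whose whole disc neighbourhood is foreground."""
    out = np.zeros_like(mask)
    offs = [(dr, dc)
            for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1)
            if dr * dr + dc * dc <= radius * radius]
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and all(
                0 <= r + dr < h and 0 <= c + dc < w and mask[r + dr, c + dc]
                for dr, dc in offs
            ):
                out[r, c] = True
    return out


class TestClusterCount:
    def test_single_disc(self):
        assert cluster_count(disc_mask((64, 64), (31, 31), 12), 3.0) == 1

    def test_bridged_discs_split_by_erosion(self):
        m = disc_mask((64, 64), (31, 15), 10) | disc_mask((64, 64), (31, 48), 10)
        m[30:32, 15:48] = True  # 2-px bridge
        from scipy import ndimage
        eroded = _brute_erosion(m, 3)
        n_oracle = ndimage.label(eroded, structure=np.ones((3, 3)))[1]
        assert n_oracle == 2
        assert cluster_count(m, 3.0) == 2

    def test_radius_zero_is_component_count(self):
        m = disc_mask((64, 64), (20, 20), 5) | disc_mask((64, 64), (45, 45), 5)
        assert cluster_count(m, 0.0) == 2

    def test_erosion_wipes_small_mask(self):
        m = disc_mask((32, 32), (15, 15), 3)
        assert cluster_count(m, 10.0) == 0


class TestShapeMetricsBundle:
    def test_initial_circular_plasmodium(self):
        m = disc_mask((181, 181), (90, 90), 70)
        s = shape_metrics(m, mm_per_px=0.5, erosion_radius_mm=1.0)
        assert s.C == pytest.approx(1.0, rel=0.02)
        assert s.E == pytest.approx(0.0, abs=0.02)
        assert s.S == pytest.approx(1.0, rel=0.02)
        assert s.n_clusters == 1
        assert s.A == pytest.approx(np.pi * 35**2, rel=0.01)  # mm^2
        assert s.C == pytest.approx(s.P**2 / (4 * np.pi * s.A), rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            shape_metrics(np.zeros((10, 10), bool))
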