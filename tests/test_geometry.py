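"""Second-moment ellipse fit: hand-computed moments, recovery, invariances."""

import math

import numpy as np
import pytest

from morphomig import TrackConfig, central_moments, fit_second_moment_ellipse
from morphomig.synthetic import render_ellipse_mask

from conftest import frame_from_array


def brute_force_ellipse(mask):
    """Independent oracle: eigendecomposition of the pixel-coordinate covariance.

    Returns (cx, cy, full_minor, full_major, orientation_deg in [0, 180)).
    """
    ys, xs = np.nonzero(mask)
    coords = np.stack([xs, ys]).astype(float)
    c = coords.mean(axis=1)
    cov = (coords - c[:, None]) @ (coords - c[:, None]).T / coords.shape[1]
    lam, vec = np.linalg.eigh(cov)  # ascending eigenvalues
    major_vec = vec[:, 1]
    phi = math.degrees(math.atan2(major_vec[1], major_vec[0])) % 180.0
    return c[0], c[1], 4.0 * math.sqrt(max(lam[0], 0)), 4.0 * math.sqrt(lam[1]), phi


def angdiff(a, b):
    """Smallest difference between two undirected axis angles, degrees."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


class TestCentralMoments:
    def test_single_pixel_is_a_point_mass(self):
        arr = np.zeros((10, 10), bool)
        arr[7, 5] = True  # row y=7, col x=5
        m00, cx, cy, mu20, mu11, mu02 = central_moments(frame_from_array(arr))
        assert (m00, cx, cy) == (1, 5, 7)
        assert mu20 == mu11 == mu02 == 0

    def test_horizontal_bar_hand_sum(self):
        # pixels at (x, y) = (0,0), (1,0), (2,0): centroid (1, 0), var_x = 2/3
        arr = np.zeros((3, 5), bool)
        arr[0, 0:3] = True
        m00, cx, cy, mu20, mu11, mu02 = central_moments(frame_from_array(arr))
        assert m00 == 3
        assert (cx, cy) == (1.0, 0.0)
        assert mu20 == pytest.approx(2.0 / 3.0)
        assert mu02 == 0.0
        assert mu11 == 0.0

    def test_translation_shifts_centroid_only(self, unit_config):
        rng = np.random.default_rng(0)
        arr = np.zeros((64, 64), bool)
        arr[20:35, 10:40] = rng.random((15, 30)) > 0.3
        moved = np.roll(arr, (7, -3), axis=(0, 1))
        m = central_moments(frame_from_array(arr))
        mm = central_moments(frame_from_array(moved))
        assert mm[0] == m[0]
        assert mm[1] == m[1] - 3 and mm[2] == m[2] + 7
        assert mm[3:] == m[3:]

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            central_moments(frame_from_array(np.zeros((5, 5), bool)))


class TestEllipseFit:
    def test_disc_is_round_with_in_range_orientation(self, unit_config):
        mask = render_ellipse_mask((64, 64), 40, 40, 0.0, (128, 128))
        shape = fit_second_moment_ellipse(frame_from_array(mask), unit_config)
        assert shape.elongation_eps <= 0.01
        assert 0.0 <= shape.orientation_phi_deg < 180.0
        assert not shape.degenerate

    def test_recovers_rasterized_ellipse_and_matches_oracle(self, unit_config):
        mask = render_ellipse_mask((100, 100), 20, 60, 30.0, (200, 200))
        shape = fit_second_moment_ellipse(frame_from_array(mask), unit_config)
        assert angdiff(shape.orientation_phi_deg, 30.0) < 1.0
        assert shape.elongation_eps == pytest.approx(1.0 - 20.0 / 60.0, abs=0.02)
        cx, cy, a, b, phi = brute_force_ellipse(mask)
        assert shape.centroid_x_um == pytest.approx(cx, rel=1e-9)
        assert shape.centroid_y_um == pytest.approx(cy, rel=1e-9)
        assert shape.minor_axis_a_um == pytest.approx(a, rel=1e-9)
        assert shape.major_axis_b_um == pytest.approx(b, rel=1e-9)
        assert angdiff(shape.orientation_phi_deg, phi) < 1e-9

    def test_quarter_turn_equivariance(self, unit_config):
        mask = render_ellipse_mask((100, 100), 20, 60, 25.0, (200, 200))
        rotated = np.rot90(mask)  # exact 90° rotation of the grid
        s1 = fit_second_moment_ellipse(frame_from_array(mask), unit_config)
        s2 = fit_second_moment_ellipse(frame_from_array(rotated), unit_config)
        assert angdiff(s2.orientation_phi_deg, (s1.orientation_phi_deg + 90.0) % 180.0) < 1.0
        assert s2.elongation_eps == pytest.approx(s1.elongation_eps, abs=0.02)

    def test_elongation_is_scale_invariant(self, unit_config):
        mask = render_ellipse_mask((80, 80), 15, 45, 40.0, (160, 160))
        up = np.kron(mask, np.ones((2, 2), bool))  # 2x nearest-neighbour upsample
        e1 = fit_second_moment_ellipse(frame_from_array(mask), unit_config).elongation_eps
        e2 = fit_second_moment_ellipse(frame_from_array(up), unit_config).elongation_eps
        assert abs(e1 - e2) < 0.01

    def test_physical_units_scale_with_pixel_size(self, calibrated_config):
        mask = render_ellipse_mask((100, 100), 20, 60, 0.0, (200, 200))
        px = calibrated_config.pixel_size_um
        shape = fit_second_moment_ellipse(frame_from_array(mask, pixel_size=px),
                                          calibrated_config)
        assert shape.area_um2 == pytest.approx(mask.sum() * px * px)
        # lengths in µm ≈ 2·semi-axis·px; elongation dimensionless
        assert shape.major_axis_b_um == pytest.approx(4 * 30.0 * px, rel=0.05)

    def test_degenerate_line_is_clamped_and_flagged(self, unit_config):
        arr = np.zeros((10, 10), bool)
        arr[4, 2:9] = True  # 1-pixel-wide line: zero minor second moment
        shape = fit_second_moment_ellipse(frame_from_array(arr), unit_config)
        assert shape.degenerate
        assert shape.minor_axis_a_um >= 1.0  # clamped to half a pixel semi-axis

    def test_oracle_agreement_on_random_blobs(self, unit_config):
        rng = np.random.default_rng(42)
        for _ in range(10):
            mask = render_ellipse_mask(
                (128, 128),
                rng.uniform(10, 25),
                rng.uniform(30, 55),
                rng.uniform(0, 180),
                (256, 256),
            )
            shape = fit_second_moment_ellipse(frame_from_array(mask), unit_config)
            cx, cy, a, b, phi = brute_force_ellipse(mask)
            assert shape.minor_axis_a_um == pytest.approx(a, rel=1e-9)
            assert shape.major_axis_b_um == pytest.approx(b, rel=1e-9)
            assert angdiff(shape.orientation_phi_deg, phi) < 1e-9

    def test_matches_skimage_regionprops_convention(self, unit_config):
        skimage = pytest.importorskip("skimage.measure")
        mask = render_ellipse_mask((90, 110), 18, 50, 70.0, (220, 220))
        shape = fit_second_moment_ellipse(frame_from_array(mask), unit_config)
        props = skimage.regionprops(mask.astype(np.uint8))[0]
        assert shape.major_axis_b_um == pytest.approx(props.axis_major_length, rel=1e-6)
        assert shape.minor_axis_a_um == pytest.approx(props.axis_minor_length, rel=1e-6)
        # skimage measures orientation from the row axis, counterclockwise
        phi_sk = (90.0 - math.degrees(props.orientation)) % 180.0
        assert angdiff(shape.orientation_phi_deg, phi_sk) < 1e-6
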