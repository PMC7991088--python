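"""Per-frame FRET geometry: distances, dipoles, kappa^2, Foerster efficiency."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy.spatial.transform import Rotation

from fretforge.geometry import (
    DegenerateGeometryError,
    ForsterParams,
    LabeledFrame,
    batch_observables,
    dipole_direction,
    frame_observables,
    fret_efficiency,
    kappa2_orientation_scan,
    kappa_squared,
    separation,
)

PARAMS = ForsterParams(r0_iso=4.9)

finite_coord = st.floats(-50.0, 50.0, allow_nan=False, allow_infinity=False)
vec3 = st.tuples(finite_coord, finite_coord, finite_coord).map(np.array)


def random_frame(rng) -> LabeledFrame:
    pts = rng.normal(scale=3.0, size=(4, 3))
    pts[2] += np.array([0.0, 0.0, 6.0])  # keep centers apart
    return LabeledFrame(
        time=0.0,
        donor_center=pts[0],
        donor_tip=pts[0] + rng.normal(size=3) + 0.5,
        acceptor_center=pts[2],
        acceptor_tip=pts[2] + rng.normal(size=3) + 0.5,
    )


class TestSeparation:
    def test_axis_aligned(self):
        f = LabeledFrame(0.0, [0, 0, 0], [1, 0, 0], [0, 0, 6.0], [0, 0, 7.0])
        d, u = separation(f)
        assert d == pytest.approx(6.0)
        assert u == pytest.approx([0, 0, 1])

    def test_3_4_5_triangle(self):
        a = np.array([1.0, 1.0, 1.0])
        b = a + np.array([3.0, 4.0, 0.0]) * 0.1
        f = LabeledFrame(0.0, a, a + 1, b, b + 1)
        d, _ = separation(f)
        assert d == pytest.approx(0.5)

    def test_coincident_centers_error(self):
        f = LabeledFrame(0.0, [0, 0, 0], [1, 0, 0], [0, 0, 0.0], [0, 1, 0])
        with pytest.raises(DegenerateGeometryError):
            separation(f)

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            f = random_frame(rng)
            d, _ = separation(f)
            # scalar oracle: explicit component loop
            acc = 0.0
            for i in range(3):
                acc += (f.acceptor_center[i] - f.donor_center[i]) ** 2
            assert d == pytest.approx(acc**0.5, rel=1e-12)


class TestDipoleDirection:
    @pytest.mark.parametrize(
        "center,tip,expected",
        [
            ([0, 0, 0], [2, 0, 0], [1, 0, 0]),
            ([0, 0, 0], [1, 1, 0], [np.sqrt(2) / 2, np.sqrt(2) / 2, 0]),
        ],
    )
    def test_examples(self, center, tip, expected):
        assert dipole_direction(center, tip) == pytest.approx(expected)

    def test_zero_length_error(self):
        with pytest.raises(DegenerateGeometryError):
            dipole_direction([1, 2, 3], [1, 2, 3])

    @given(c=vec3, t=vec3)
    @settings(max_examples=100, derandomize=True)
    def test_unit_norm(self, c, t):
        assume(np.linalg.norm(t - c) > 1e-6)  # physically meaningful dipole length
        u = dipole_direction(c, t)
        assert abs(np.linalg.norm(u) - 1.0) < 1e-12


class TestKappaSquared:
    def test_collinear_head_to_tail_is_4(self):
        z = np.array([0.0, 0.0, 1.0])
        assert kappa_squared(z, z, z) == pytest.approx(4.0)

    def test_mutually_perpendicular_is_0(self):
        x, y, z = np.eye(3)
        assert kappa_squared(x, y, z) == pytest.approx(0.0)

    def test_parallel_perpendicular_to_separation_is_1(self):
        x, _, z = np.eye(3)[0], None, np.eye(3)[2]
        assert kappa_squared(x, x, z) == pytest.approx(1.0)

    def test_non_unit_input_rejected(self):
        z = np.array([0.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            kappa_squared(2 * z, z, z)

    def test_sign_flip_invariance_and_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            v = rng.standard_normal((3, 3))
            v /= np.linalg.norm(v, axis=1)[:, None]
            d, a, r = v
            k2 = kappa_squared(d, a, r)
            assert 0.0 <= k2 <= 4.0
            assert kappa_squared(-d, a, r) == pytest.approx(k2)
            assert kappa_squared(d, -a, r) == pytest.approx(k2)

    def test_isotropic_average_two_thirds(self):
        rng = np.random.default_rng(7)
        n = 200_000
        d = rng.standard_normal((n, 3))
        a = rng.standard_normal((n, 3))
        d /= np.linalg.norm(d, axis=1)[:, None]
        a /= np.linalg.norm(a, axis=1)[:, None]
        r = np.array([0.0, 0.0, 1.0])
        kappa = np.einsum("ij,ij->i", d, a) - 3.0 * (d @ r) * (a @ r)
        assert (kappa**2).mean() == pytest.approx(2.0 / 3.0, abs=0.02)

    def test_orientation_scan_extremes(self):
        lo, hi = kappa2_orientation_scan(n_polar=51, n_azimuth=61)
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(4.0, abs=1e-9)


class TestFretEfficiency:
    def test_forster_radius_identity(self):
        assert fret_efficiency(4.9, 2.0 / 3.0, PARAMS) == 0.5

    def test_zero_kappa2_gives_zero(self):
        assert fret_efficiency(3.0, 0.0, PARAMS) == 0.0

    def test_double_distance_closed_form(self):
        # E = 1 / (1 + 2^6) at D = 2 R0, kappa^2 = 2/3
        assert fret_efficiency(2 * 4.9, 2.0 / 3.0, PARAMS) == pytest.approx(1 / 65)

    def test_nonpositive_distance_error(self):
        with pytest.raises(ValueError):
            fret_efficiency(0.0, 1.0, PARAMS)

    @given(
        d1=st.floats(0.5, 15.0),
        d2=st.floats(0.5, 15.0),
        k1=st.floats(0.01, 4.0),
        k2=st.floats(0.01, 4.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotonicity(self, d1, d2, k1, k2):
        if d1 != d2:
            lo, hi = sorted((d1, d2))
            assert fret_efficiency(lo, k1, PARAMS) > fret_efficiency(hi, k1, PARAMS)
        if k1 != k2:
            klo, khi = sorted((k1, k2))
            assert fret_efficiency(d1, klo, PARAMS) < fret_efficiency(d1, khi, PARAMS)


class TestFrameObservables:
    def test_collinear_at_r0(self):
        z = np.array([0.0, 0.0, 1.0])
        f = LabeledFrame(0.0, [0, 0, 0], z, [0, 0, 4.9], [0, 0, 4.9 + 1])
        obs = frame_observables(f, PARAMS)
        assert obs.kappa2 == pytest.approx(4.0)
        assert obs.efficiency == pytest.approx(6.0 / 7.0)

    def test_perpendicular_geometry_zero_efficiency(self):
        f = LabeledFrame(0.0, [0, 0, 0], [1, 0, 0], [0, 0, 6.0], [0, 1, 6.0])
        obs = frame_observables(f, PARAMS)
        assert obs.kappa2 == pytest.approx(0.0)
        assert obs.efficiency == pytest.approx(0.0)

    def test_batch_equals_scalar_oracle(self):
        rng = np.random.default_rng(3)
        frames = [random_frame(rng) for _ in range(500)]
        d, k2, e = batch_observables(
            np.zeros(len(frames)),
            np.array([f.donor_center for f in frames]),
            np.array([f.donor_tip for f in frames]),
            np.array([f.acceptor_center for f in frames]),
            np.array([f.acceptor_tip for f in frames]),
            PARAMS,
        )
        for i, f in enumerate(frames):
            obs = frame_observables(f, PARAMS)
            assert d[i] == pytest.approx(obs.distance, rel=1e-10)
            assert k2[i] == pytest.approx(obs.kappa2, rel=1e-10, abs=1e-12)
            assert e[i] == pytest.approx(obs.efficiency, rel=1e-10, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        f = random_frame(rng)
        obs = frame_observables(f, PARAMS)
        rot = Rotation.random(random_state=5)
        shift = np.array([1.0, -2.0, 3.0])

        def move(p):
            return rot.apply(p) + shift

        g = LabeledFrame(
            f.time,
            move(f.donor_center),
            move(f.donor_tip),
            move(f.acceptor_center),
            move(f.acceptor_tip),
        )
        obs2 = frame_observables(g, PARAMS)
        assert obs2.distance == pytest.approx(obs.distance, rel=1e-10)
        assert obs2.kappa2 == pytest.approx(obs.kappa2, rel=1e-8, abs=1e-10)
        assert obs2.efficiency == pytest.approx(obs.efficiency, rel=1e-8, abs=1e-10)
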