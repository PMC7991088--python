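"""Running averages, ensemble means, delta-FRET, breakdowns, RMSD, histograms."""

import itertools

import numpy as np
import pytest

from fretforge import GeneratorConfig, simulate_tether
from fretforge.ensemble import (
    conformer_breakdown,
    d_histogram,
    delta_fret,
    ensemble_mean,
    rmsd_trace,
    running_average,
)

from conftest import make_record


class TestRunningAverage:
    def test_constant_series(self):
        rec = make_record(np.full(500, 0.3))
        out = running_average([rec], window_ns=10.0)
        assert np.allclose(out["mean_e"], 0.3)

    def test_alternating_series_window_two_frames(self):
        rec = make_record(np.tile([0.0, 1.0], 50))
        out = running_average([rec], window_ns=0.2)  # 2 frames at 100 ps
        assert np.allclose(out["mean_e"], 0.5)

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(0)
        e = rng.uniform(size=300)
        rec = make_record(e)
        w = 25
        out = running_average([rec], window_ns=w * 0.1)
        expected = [sum(e[i : i + w]) / w for i in range(len(e) - w + 1)]
        assert np.allclose(out["mean_e"], expected, atol=1e-12)

    def test_window_of_one_frame_reproduces_raw(self):
        rng = np.random.default_rng(1)
        e = rng.uniform(size=100)
        out = running_average([make_record(e)], window_ns=0.1)
        assert np.allclose(out["mean_e"], e)

    def test_mixed_states_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            running_average(
                [make_record([0.1] * 10, state="bound"), make_record([0.2] * 10, state="free")]
            )

    def test_window_shorter_than_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            running_average([make_record([0.1] * 10)], window_ns=0.01)

    def test_concatenated_mode_windows_across_junctions(self):
        a = make_record(np.zeros(10), conformer_id="a")
        b = make_record(np.ones(10), conformer_id="b")
        lit = running_average([a, b], window_ns=0.4, mode="concatenated")
        sep = running_average([a, b], window_ns=0.4, mode="per_conformer")
        # literal mode has windows mixing the junction (values strictly between 0 and 1)
        assert ((lit["mean_e"] > 0) & (lit["mean_e"] < 1)).any()
        assert not ((sep["mean_e"] > 0) & (sep["mean_e"] < 1)).any()


class TestEnsembleMean:
    def test_order_independence(self):
        rng = np.random.default_rng(2)
        recs = [
            make_record(rng.uniform(size=rng.integers(50, 150)), conformer_id=f"c{i}")
            for i in range(4)
        ]
        ref, _ = ensemble_mean(recs, burn_in_ms=1e-9, window_ns=0.5)
        for perm in itertools.permutations(recs):
            m, _ = ensemble_mean(list(perm), burn_in_ms=1e-9, window_ns=0.5)
            assert abs(m - ref) < 1e-12

    def test_constant_record_zero_sd(self):
        m, sd = ensemble_mean([make_record(np.full(200, 0.4))], burn_in_ms=1e-9, window_ns=1.0)
        assert m == pytest.approx(0.4)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_burn_in_exceeding_total_time_rejected(self):
        with pytest.raises(ValueError, match="burn-in"):
            ensemble_mean([make_record([0.1] * 10)], burn_in_ms=1.0)


class TestDeltaFret:
    def test_identical_ensembles_give_zero(self):
        e = np.random.default_rng(3).uniform(size=200)
        b = make_record(e, state="bound")
        f = make_record(e, state="free", conformer_id="c1")
        d, _ = delta_fret([b], [f], burn_in_ms=1e-9, window_ns=1.0)
        assert d == pytest.approx(0.0, abs=1e-15)

    def test_subtraction_value(self):
        b = make_record(np.full(100, 0.40), state="bound")
        f = make_record(np.full(100, 0.18), state="free", conformer_id="c1")
        d, sd = delta_fret([b], [f], burn_in_ms=1e-9, window_ns=1.0)
        assert d == pytest.approx(0.22)
        assert 100 * d == pytest.approx(22.0)

    def test_missing_state_rejected(self):
        b = make_record([0.1] * 10, state="bound")
        with pytest.raises(ValueError):
            delta_fret([b], [], burn_in_ms=1e-9)
        with pytest.raises(ValueError):
            delta_fret([b], [b], burn_in_ms=1e-9)


class TestConformerBreakdown:
    def test_static_conformer_flagged_trapped(self):
        mobile = make_record(
            np.full(100, 0.2), distance=np.linspace(5, 8, 100), conformer_id="mobile"
        )
        static = make_record(
            np.full(100, 0.2), distance=np.full(100, 6.0), conformer_id="static"
        )
        df = conformer_breakdown([mobile, static]).set_index("conformer_id")
        assert bool(df.loc["static", "trapped"])
        assert df.loc["static", "d_range_nm"] == 0.0
        assert not bool(df.loc["mobile", "trapped"])

    def test_fast_isotropic_conformer_full_kappa2_coverage(self, short_bound_record):
        df = conformer_breakdown([short_bound_record])
        assert df["kappa2_coverage"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_basins_separate_mean_d(self):
        lo = make_record(np.full(50, 0.3), distance=np.random.default_rng(0).normal(5, 0.1, 50), conformer_id="lo")
        hi = make_record(np.full(50, 0.1), distance=np.random.default_rng(1).normal(8, 0.1, 50), conformer_id="hi")
        df = conformer_breakdown([lo, hi]).set_index("conformer_id")
        assert df.loc["hi", "mean_d_nm"] - df.loc["lo", "mean_d_nm"] > 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            conformer_breakdown([])


class TestRmsdTrace:
    def test_frame_vs_itself_zero(self):
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        out = rmsd_trace(ref[None], ref)
        assert out["rmsd_nm"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_translation(self):
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        moved = ref + np.array([0.3, -0.4, 0.0])
        on = rmsd_trace(moved[None], ref, superpose=True)
        off = rmsd_trace(moved[None], ref, superpose=False)
        assert on["rmsd_nm"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert off["rmsd_nm"].iloc[0] == pytest.approx(0.5)  # |(0.3,-0.4,0)|

    def test_rigid_rotation_superposed_to_zero(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(4)
        ref = rng.normal(size=(6, 3))
        rot = Rotation.random(random_state=8)
        out = rmsd_trace(rot.apply(ref)[None], ref, superpose=True)
        assert out["rmsd_nm"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_three_point_hand_computed(self):
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        frame = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 1]])  # one atom moved 1 nm
        out = rmsd_trace(frame[None], ref, superpose=False)
        assert out["rmsd_nm"].iloc[0] == pytest.approx(np.sqrt(1.0 / 3.0), rel=1e-12)

    def test_atom_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmsd_trace(np.zeros((1, 4, 3)), np.zeros((3, 3)))


class TestDHistogram:
    def test_generator_output_has_zero_band_mass(self, short_bound_record):
        h = d_histogram([short_bound_record])
        assert h.band_mass == 0.0

    def test_uniform_distances_flat(self):
        rng = np.random.default_rng(5)
        rec = make_record(np.full(20000, 0.2), distance=rng.uniform(5, 8, 20000))
        h = d_histogram([rec], bin_width_nm=0.5)
        interior = h.density[1:-1]  # edge bins may be partially covered
        assert np.all(np.abs(interior - 1.0 / 3.0) < 0.05)

    def test_all_equal_single_bin(self):
        rec = make_record(np.full(50, 0.2), distance=np.full(50, 6.05))
        h = d_histogram([rec], bin_width_nm=0.1)
        assert (h.density > 0).sum() == 1

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            d_histogram([make_record([0.2])], bin_width_nm=0.0)
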