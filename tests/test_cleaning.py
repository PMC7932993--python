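"""Invalid-observation detection and imputation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import posemotion as pm
from posemotion.cleaning import UnimputablePointError


def column_sequence(x_vals, c_vals=None, model=None, fps=25.0):
    """One-point toy sequence (y mirrors x offset by 100)."""
    model = model or pm.KeypointModelSpec("p1", 1, ("only",), "pose_keypoints_2d")
    x = np.asarray(x_vals, dtype=float).reshape(-1, 1)
    y = x + 100.0
    c = (
        np.ones_like(x)
        if c_vals is None
        else np.asarray(c_vals, dtype=float).reshape(-1, 1)
    )
    return pm.PoseSequence(model, x, y, c, fps=fps)


class TestFindInvalid:
    def test_all_zero_triplet_is_invalid(self):
        seq = column_sequence([5.0, 0.0, 5.0])
        seq.x[1] = seq.y[1] = seq.c[1] = 0.0
        mask = pm.find_invalid(seq)
        assert mask.valid[:, 0].tolist() == [True, False, True]

    def test_strict_cutoff_boundary(self):
        # c = 0.29 imputed, c = 0.30 kept: strict "< cutoff"
        seq = column_sequence([100.0, 100.0], c_vals=[0.29, 0.30])
        mask = pm.find_invalid(seq, cutoff=0.3)
        assert mask.valid[:, 0].tolist() == [False, True]

    def test_full_confidence_is_all_valid(self):
        seq = column_sequence([1.0, 2.0, 3.0])
        assert pm.find_invalid(seq).valid.all()

    def test_zero_coordinate_alone_is_valid(self):
        # only the *triple* zero marks a failed fit
        seq = column_sequence([0.0, 1.0], c_vals=[0.9, 0.9])
        seq.y[0] = 0.0  # x=0, y=100->0, c=0.9
        assert pm.find_invalid(seq).valid.all()

    @pytest.mark.parametrize("cutoff", [-0.1, 1.5])
    def test_cutoff_domain(self, cutoff):
        seq = column_sequence([1.0, 2.0])
        with pytest.raises(ValueError, match="cutoff"):
            pm.find_invalid(seq, cutoff=cutoff)


class TestImpute:
    def test_isolated_gap_gets_neighbour_mean(self):
        seq = column_sequence([2.0, -1.0, 4.0], c_vals=[1, 0.1, 1])
        cleaned, _ = pm.clean(seq)
        assert cleaned.x[1, 0] == 3.0
        assert cleaned.y[1, 0] == 103.0

    def test_leading_boundary_fills_nearest_valid(self):
        seq = column_sequence([0.0, 7.0, 7.0], c_vals=[0.0, 1, 1])
        seq.y[0] = 0.0
        cleaned, _ = pm.clean(seq)
        assert cleaned.x[0, 0] == 7.0

    def test_trailing_boundary_fills_nearest_valid(self):
        seq = column_sequence([3.0, 5.0, -9.0], c_vals=[1, 1, 0.2])
        cleaned, _ = pm.clean(seq)
        assert cleaned.x[2, 0] == 5.0

    def test_affine_run_recovered_exactly(self):
        # x_t = 10 + 2t, frames 3-5 dropped -> interpolation is exact
        t = np.arange(10)
        truth = 10.0 + 2.0 * t
        c = np.ones(10)
        c[3:6] = 0.05
        seq = column_sequence(truth, c_vals=c)
        cleaned, _ = pm.clean(seq)
        np.testing.assert_allclose(cleaned.x[:, 0], truth, atol=1e-9)
        np.testing.assert_allclose(cleaned.y[:, 0], truth + 100, atol=1e-9)

    def test_valid_cells_untouched_and_confidence_preserved(self, rng):
        x = rng.uniform(0, 640, (20, 25))
        y = rng.uniform(0, 480, (20, 25))
        c = rng.uniform(0.6, 1.0, x.shape)
        c[rng.random(c.shape) < 0.2] = 0.1
        seq = pm.PoseSequence(pm.BODY25, x, y, c, fps=25)
        mask = pm.find_invalid(seq)
        cleaned, _ = pm.impute(seq, mask)
        np.testing.assert_array_equal(cleaned.x[mask.valid], x[mask.valid])
        np.testing.assert_array_equal(cleaned.y[mask.valid], y[mask.valid])
        np.testing.assert_array_equal(cleaned.c, c)

    def test_idempotent_on_values(self, rng):
        x = rng.uniform(0, 640, (15, 5))
        c = rng.uniform(0.6, 1.0, x.shape)
        c[rng.random(c.shape) < 0.3] = 0.0
        c[0, :] = 1.0  # keep every point imputable
        model = pm.KeypointModelSpec(
            "toy5", 5, tuple("abcde"), "pose_keypoints_2d"
        )
        seq = pm.PoseSequence(model, x, x.copy(), c, fps=25)
        once, _ = pm.clean(seq)
        twice, _ = pm.clean(once)
        np.testing.assert_array_equal(once.x, twice.x)
        np.testing.assert_array_equal(once.y, twice.y)

    def test_point_with_no_valid_observation_raises(self):
        seq = column_sequence([1.0, 2.0, 3.0], c_vals=[0.1, 0.1, 0.1])
        with pytest.raises(UnimputablePointError, match="only"):
            pm.clean(seq)

    @given(
        dropout=st.sets(st.integers(1, 18), max_size=12),
        slope=st.floats(-5, 5),
        intercept=st.floats(-100, 100),
    )
    def test_affine_recovery_property(self, dropout, slope, intercept):
        """Any interior dropout pattern on an affine trajectory is invisible
        after cleaning."""
        t = np.arange(20, dtype=float)
        truth = intercept + slope * t
        c = np.ones(20)
        c[list(dropout)] = 0.0
        seq = column_sequence(truth, c_vals=c)
        cleaned, _ = pm.clean(seq)
        np.testing.assert_allclose(cleaned.x[:, 0], truth, atol=1e-9)


class TestCleanFile:
    def test_suffix_and_roundtrip(self, tmp_path, rng):
        x = rng.uniform(1, 640, (10, 25))
        c = np.ones_like(x)
        c[4, 7] = 0.0
        seq = pm.PoseSequence(pm.BODY25, x, x.copy(), c, fps=25)
        src = tmp_path / "clip_body25.csv"
        pm.write_table(seq, src)
        out = pm.clean_file(src)
        assert out.name == "clip_body25_cleaned.csv"
        cleaned = pm.read_table(out)
        expected = (x[3, 7] + x[5, 7]) / 2
        assert cleaned.x[4, 7] == pytest.approx(expected, abs=1e-12)

    def test_overwrite_replaces_input(self, tmp_path, rng):
        x = rng.uniform(1, 640, (5, 25))
        seq = pm.PoseSequence(pm.BODY25, x, x.copy(), np.ones_like(x), fps=25)
        src = tmp_path / "clip_body25.csv"
        pm.write_table(seq, src)
        out = pm.clean_file(src, overwrite=True)
        assert out == src
        assert list(tmp_path.iterdir()) == [src]

    def test_clean_input_is_numerically_identical(self, tmp_path, rng):
        x = rng.uniform(1, 640, (8, 25))
        seq = pm.PoseSequence(pm.BODY25, x, x.copy(), np.ones_like(x), fps=25)
        src = tmp_path / "clip_body25.csv"
        pm.write_table(seq, src)
        out = pm.clean_file(src)
        assert pm.read_table(out) == pm.read_table(src)

    def test_bad_cutoff_writes_nothing(self, tmp_path, rng):
        x = rng.uniform(1, 640, (5, 25))
        seq = pm.PoseSequence(pm.BODY25, x, x.copy(), np.ones_like(x), fps=25)
        src = tmp_path / "clip_body25.csv"
        pm.write_table(seq, src)
        with pytest.raises(ValueError, match="cutoff"):
            pm.clean_file(src, cutoff=1.5)
        assert list(tmp_path.iterdir()) == [src]
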