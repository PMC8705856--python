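import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wheelbouts import ddr, io
from wheelbouts.errors import InsufficientDataError
from wheelbouts.evaluate import load_table1_moving


def _recording(ax, ay=None, az=None):
    n = len(ax)
    ay = ay if ay is not None else np.zeros(n)
    az = az if az is not None else np.zeros(n)
    return io.RawRecording(t_us=np.arange(n) * 50_000, ax=ax, ay=ay, az=az)


def _mag(values):
    values = np.asarray(values, dtype=float)
    return ddr.MagnitudeSequence(d=values, t_s=np.arange(len(values), dtype=float))


class TestDifferentiate:
    def test_published_moving_column_row_by_row(self):
        """The printed example: raw moving readings -> printed differences."""
        t1 = load_table1_moving()
        raw = t1["raw"].to_numpy(dtype=float)
        printed = t1["diff_printed"].dropna().to_numpy(dtype=float)
        out = ddr.differentiate(_recording(np.zeros(len(raw)), ay=raw))
        np.testing.assert_allclose(out.ry, printed, atol=1e-5)

    def test_constant_axis_gives_zeros(self):
        out = ddr.differentiate(_recording(np.full(6, 3.3)))
        assert np.all(out.rx == 0)

    def test_matches_elementwise_loop_oracle(self, rng):
        vals = rng.normal(size=(6, 3))
        rec = _recording(vals[:, 0], vals[:, 1], vals[:, 2])
        out = ddr.differentiate(rec)
        for i in range(5):
            assert out.rx[i] == vals[i + 1, 0] - vals[i, 0]
            assert out.ry[i] == vals[i + 1, 1] - vals[i, 1]
            assert out.rz[i] == vals[i + 1, 2] - vals[i, 2]

    def test_length_shrinks_by_one_and_times_are_later_samples(self, rng):
        rec = _recording(rng.normal(size=10))
        out = ddr.differentiate(rec)
        assert len(out) == 9
        np.testing.assert_allclose(out.t_s, rec.t_s[1:])

    @given(st.integers(-5, 5))
    def test_constant_offset_cancels(self, offset):
        rng = np.random.default_rng(42)
        vals = rng.normal(size=8)
        base = ddr.differentiate(_recording(vals))
        shifted = ddr.differentiate(_recording(vals + offset))
        np.testing.assert_allclose(shifted.rx, base.rx, atol=1e-12)


class TestCombineAxes:
    @pytest.mark.parametrize(
        "xyz,expected", [((0, 0, 0), 0.0), ((3, 4, 0), 5.0), ((1, 2, 2), 3.0)]
    )
    def test_known_magnitudes(self, xyz, expected):
        d = ddr.DifferentiatedRecording(
            rx=np.array([float(xyz[0])]), ry=np.array([float(xyz[1])]),
            rz=np.array([float(xyz[2])]), t_s=np.array([0.0]),
        )
        assert ddr.combine_axes(d).d[0] == pytest.approx(expected)

    @given(st.permutations([0, 1, 2]), st.tuples(*[st.sampled_from([-1.0, 1.0])] * 3))
    def test_invariant_under_axis_permutation_and_sign_flip(self, perm, signs):
        """Placement invariance: the fused magnitude ignores how the device
        was oriented."""
        rng = np.random.default_rng(7)
        axes = rng.normal(size=(3, 5))
        base = ddr.combine_axes(
            ddr.DifferentiatedRecording(axes[0], axes[1], axes[2], np.arange(5.0))
        )
        tr = [axes[p] * s for p, s in zip(perm, signs)]
        out = ddr.combine_axes(
            ddr.DifferentiatedRecording(tr[0], tr[1], tr[2], np.arange(5.0))
        )
        np.testing.assert_allclose(out.d, base.d, rtol=1e-12)


class TestOutlierHandling:
    def test_all_equal_sequence(self):
        b = ddr.outlier_bounds(_mag([2.0] * 8))
        assert b.iqr == 0
        assert b.upper == 2.0

    def test_against_interpolated_quartile_oracle(self):
        vals = np.arange(1.0, 13.0)

        def quantile_oracle(x, q):
            # linear interpolation between order statistics
            x = np.sort(x)
            pos = q * (len(x) - 1)
            lo = int(np.floor(pos))
            hi = int(np.ceil(pos))
            return x[lo] + (pos - lo) * (x[hi] - x[lo])

        b = ddr.outlier_bounds(_mag(vals))
        assert b.q1 == pytest.approx(quantile_oracle(vals, 0.25), abs=1e-9)
        assert b.q2 == pytest.approx(quantile_oracle(vals, 0.50), abs=1e-9)
        assert b.q3 == pytest.approx(quantile_oracle(vals, 0.75), abs=1e-9)
        assert b.upper == pytest.approx(b.q3 + 1.5 * (b.q3 - b.q1), abs=1e-9)

    @given(st.lists(st.floats(0, 100), min_size=4, max_size=25))
    def test_quartile_ordering_invariants(self, vals):
        b = ddr.outlier_bounds(_mag(vals))
        assert b.q1 <= b.q2 <= b.q3
        assert b.iqr >= 0
        assert b.upper >= b.q3

    def test_clip_is_noop_without_outliers(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        out = ddr.clip_outliers(_mag(vals))
        np.testing.assert_array_equal(out.d, vals)

    def test_single_huge_value_clipped_to_upper(self):
        vals = [1.0, 2.0, 3.0, 4.0, 100.0]
        upper = ddr.outlier_bounds(_mag(vals)).upper
        out = ddr.clip_outliers(_mag(vals))
        assert out.d[-1] == pytest.approx(upper)
        np.testing.assert_array_equal(out.d[:-1], vals[:-1])

    @given(st.lists(st.floats(0, 1e6), min_size=4, max_size=30))
    def test_clipped_maximum_never_exceeds_upper(self, vals):
        upper = ddr.outlier_bounds(_mag(vals)).upper
        assert ddr.clip_outliers(_mag(vals)).d.max() <= upper + 1e-9


class TestNormalize:
    def test_simple_scaling(self):
        out = ddr.normalize(_mag([0.0, 5.0, 10.0]))
        np.testing.assert_allclose(out.v, [0.0, 0.5, 1.0])

    def test_constant_maps_to_zeros(self):
        assert np.all(ddr.normalize(_mag([3.0] * 5)).v == 0)

    @given(st.floats(0.1, 50), st.floats(0, 10))
    def test_invariant_under_positive_affine_rescale(self, a, b):
        """Device sensitivity differences (scale/offset of the magnitude)
        vanish after MinMax scaling."""
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 5, size=20)
        base = ddr.normalize(_mag(vals))
        scaled = ddr.normalize(_mag(a * vals + b))
        np.testing.assert_allclose(scaled.v, base.v, atol=1e-9)

    def test_output_spans_unit_interval(self, rng):
        out = ddr.normalize(_mag(rng.uniform(1, 9, size=50)))
        assert out.v.min() == 0.0
        assert out.v.max() == 1.0


class TestPipeline:
    def test_length_and_stagewise_composition(self, series1_run):
        rec, _ = series1_run
        out = ddr.ddr_pipeline(rec)
        assert len(out) == len(rec) - 1
        manual = ddr.normalize(ddr.clip_outliers(ddr.combine_axes(ddr.differentiate(rec))))
        np.testing.assert_array_equal(out.v, manual.v)

    def test_moving_periods_score_higher_than_stationary(self, series1_run):
        rec, truth = series1_run
        out = ddr.ddr_pipeline(rec)
        moving = np.zeros(len(out), dtype=bool)
        for a, b in truth.moving_intervals():
            moving |= (out.t_s >= a) & (out.t_s < b)
        assert out.v[moving].mean() > out.v[~moving].mean()

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            ddr.ddr_pipeline(_recording(np.zeros(4)))

    def test_transformer_matches_pipeline(self, series1_run):
        rec, _ = series1_run
        X = np.column_stack([rec.ax, rec.ay, rec.az])
        out = ddr.DDRTransformer().fit(X).transform(X)[:, 0]
        np.testing.assert_allclose(out, ddr.ddr_pipeline(rec).v, atol=1e-12)
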