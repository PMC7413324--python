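"""PRD/SNR quality metrics, MOS aggregation, and effort parameters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pesodenoise import (
    EffortInputs,
    InvalidArgumentError,
    MosRatings,
    PressureSignal,
    UndefinedMetricError,
    mos,
    prd,
    ptp_breath,
    ptp_minute,
    quality_category,
    snr_db,
    wob,
)
from pesodenoise.metrics import JOULE_PER_CMH2O_L, _shoelace

FS = 100.0


class TestPrd:
    def test_identical_signals_zero(self):
        x = np.array([1.0, -2.0, 3.0])
        assert prd(x, x) == 0.0

    def test_zero_estimate_is_hundred_percent(self):
        x = np.array([1.0, -2.0, 3.0])
        assert prd(x, np.zeros(3)) == pytest.approx(100.0)

    def test_worked_example(self):
        assert prd(np.array([3.0, 4.0]), np.array([3.0, 5.0])) == pytest.approx(20.0)

    def test_zero_energy_reference_undefined(self):
        with pytest.raises(UndefinedMetricError):
            prd(np.zeros(5), np.ones(5))

    @given(st.floats(min_value=1e-6, max_value=10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_proportional_error_scales_linearly(self, eps):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=256)
        assert prd(ref, ref + eps * ref) == pytest.approx(100 * eps, rel=1e-9)


class TestSnr:
    def test_perfect_reconstruction_infinite(self):
        x = np.ones(10)
        assert math.isinf(snr_db(x, x))

    def test_equal_residual_power_zero_db(self):
        clean = np.array([1.0, 1.0, 1.0, 1.0])
        assert snr_db(clean, clean + np.array([1.0, -1.0, 1.0, -1.0])) == pytest.approx(0.0)

    def test_prd_snr_duality_for_zero_mean_reference(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=512)
        ref -= ref.mean()
        est = ref + 0.1 * rng.normal(size=512)
        assert snr_db(ref, est) == pytest.approx(-20 * np.log10(prd(ref, est) / 100),
                                                 abs=1e-9)


class TestQualityCategory:
    @pytest.mark.parametrize("value, expected", [
        (0.0, "very_good"),
        (1.5, "very_good"),
        (2.0, "very_good"),
        (4.62, "good"),     # reconstruction at light contamination
        (9.0, "good"),
        (16.24, "other"),
        (27.07, "other"),   # heavy contamination
    ])
    def test_bands(self, value, expected):
        assert quality_category(value) == expected

    def test_negative_rejected(self):
        with pytest.raises(InvalidArgumentError):
            quality_category(-0.1)


class TestMos:
    def test_perfect_ratings(self):
        res = mos(np.full((3, 4), 5))
        assert res.mos == 5.0
        assert res.error_overall == 0.0
        assert res.category == "very_good"

    def test_all_fours_is_twenty_percent_good(self):
        res = mos(np.full((2, 3), 4))
        assert res.mos == 4.0
        assert res.error_overall == pytest.approx(20.0)
        assert res.category == "good"

    def test_per_feature_aggregation(self):
        res = mos(np.array([[5], [4]]))
        assert res.mos_per_feature[0] == pytest.approx(4.5)
        assert res.error_per_feature[0] == pytest.approx(10.0)

    def test_bounds_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            table = rng.integers(1, 6, size=(rng.integers(1, 10), rng.integers(1, 6)))
            res = mos(table)
            assert 1.0 <= res.mos <= 5.0
            assert 0.0 <= res.error_overall <= 80.0

    def test_out_of_range_rating_rejected(self):
        with pytest.raises(InvalidArgumentError):
            MosRatings(np.array([[1, 6]]))


def _signal_with_deflection(shape, fs=FS):
    return PressureSignal(np.asarray(shape, dtype=float), fs)


class TestPtp:
    def test_rectangular_deflection_area(self):
        fs = 1000.0
        x = np.zeros(1202)
        x[1:1001] = -5.0  # 1 s rectangle, window starts at baseline 0
        inputs = EffortInputs(PressureSignal(x, fs), insp_windows=((0, 1002),))
        assert ptp_breath(inputs, 0) == pytest.approx(5.0, abs=0.02)

    def test_zero_deflection_zero(self):
        inputs = EffortInputs(_signal_with_deflection(np.zeros(100)),
                              insp_windows=((0, 100),))
        assert ptp_breath(inputs, 0) == 0.0

    def test_triangular_deflection_area(self):
        fs = 1000.0
        half = np.linspace(0, -4, 1001)
        x = np.concatenate([half, half[::-1][1:]])  # 2 s triangle, peak -4
        inputs = EffortInputs(PressureSignal(x, fs), insp_windows=((0, x.size),))
        assert ptp_breath(inputs, 0) == pytest.approx(4.0, abs=0.01)

    def test_doubling_duration_doubles_area(self):
        fs = 1000.0
        def rect(seconds):
            n = int(seconds * fs)
            x = np.zeros(n + 202)
            x[1:n + 1] = -3.0
            return EffortInputs(PressureSignal(x, fs), insp_windows=((0, n + 2),))
        assert ptp_breath(rect(2.0), 0) == pytest.approx(2 * ptp_breath(rect(1.0), 0),
                                                         rel=1e-3)

    def test_recoil_bound_reduces_area(self):
        fs = 100.0
        x = np.zeros(402)
        x[1:401] = -5.0
        base = EffortInputs(PressureSignal(x, fs), insp_windows=((0, 402),))
        bounded = EffortInputs(PressureSignal(x, fs), insp_windows=((0, 402),),
                               chest_wall_elastance=4.0, tidal_volume=0.5)
        assert ptp_breath(bounded, 0, apply_recoil=True) < ptp_breath(base, 0)

    def test_minute_rate_scaling(self):
        fs = 1000.0
        x = np.zeros(1202)
        x[1:1001] = -5.0
        inputs = EffortInputs(PressureSignal(x, fs), insp_windows=((0, 1002),),
                              respiratory_rate=12.0)
        assert ptp_minute(inputs) == pytest.approx(60.0, abs=0.2)

    def test_mean_of_breaths_times_rate(self):
        # two windows with PTPs ~4 and ~6 at rr=10 -> 50
        fs = 1000.0
        x = np.zeros(4000)
        x[1:1001] = -4.0
        x[2001:3001] = -6.0
        inputs = EffortInputs(PressureSignal(x, fs),
                              insp_windows=((0, 1500), (2000, 3500)),
                              respiratory_rate=10.0)
        assert ptp_minute(inputs) == pytest.approx(50.0, abs=0.3)

    def test_window_outside_record_rejected(self):
        with pytest.raises(InvalidArgumentError):
            EffortInputs(_signal_with_deflection(np.zeros(50)), insp_windows=((0, 60),))


class TestWob:
    def test_rectangular_loop(self):
        # 2 cmH2O x 0.5 L rectangle, tidal 0.5 L -> 1*0.0981/0.5 J/L
        p = np.array([0.0, 2.0, 2.0, 0.0])
        v = np.array([0.0, 0.0, 0.5, 0.5])
        inputs = EffortInputs(PressureSignal(p, FS), insp_windows=((0, 4),),
                              volume=v, tidal_volume=0.5)
        assert wob(inputs) == pytest.approx(1.0 * JOULE_PER_CMH2O_L / 0.5)

    def test_collinear_loop_is_degenerate(self):
        p = np.linspace(0, 1, 10)
        v = 2 * p
        inputs = EffortInputs(PressureSignal(p, FS), insp_windows=((0, 10),),
                              volume=v, tidal_volume=0.5)
        with pytest.warns(UserWarning, match="degenerate"):
            assert wob(inputs) == 0.0

    def test_elliptical_loop_matches_closed_form(self):
        a, b = 3.0, 0.4  # cmH2O, L semi-axes
        theta = np.linspace(0, 2 * np.pi, 10 ** 4, endpoint=False)
        assert _shoelace(b * np.cos(theta), a * np.sin(theta)) == pytest.approx(
            np.pi * a * b, rel=1e-6)

    def test_requires_volume_series(self):
        inputs = EffortInputs(_signal_with_deflection(np.zeros(10)),
                              insp_windows=((0, 10),), tidal_volume=0.5)
        with pytest.raises(InvalidArgumentError):
            wob(inputs)
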