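"""Synthetic Peso/CGO generator: morphology, mixing, noise injection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pesodenoise import (
    BreathSpec,
    CgoSpec,
    InvalidArgumentError,
    MixSpec,
    SynthSpec,
    add_wgn,
    estimate_fcgo,
    gen_cgo,
    gen_peso,
    gen_synpeso,
    mix,
    snr_db,
)

FS = 100.0


class TestGenPeso:
    def test_active_deflects_down_to_swing(self):
        sig = gen_peso(BreathSpec(mode="active", rr=15, pee=0.0, swing=5.0),
                       FS, 60.0, seed=1)
        assert sig.samples.min() == pytest.approx(-5.0, abs=0.05)
        # expiration sits near the baseline
        assert np.median(sig.samples) == pytest.approx(0.0, abs=0.5)

    def test_passive_deflects_up(self):
        sig = gen_peso(BreathSpec(mode="passive", rr=15, pee=0.0, swing=5.0),
                       FS, 60.0, seed=1)
        assert sig.samples.max() == pytest.approx(5.0, abs=0.05)

    def test_baseline_offset_carried(self):
        sig = gen_peso(BreathSpec(mode="active", rr=15, pee=8.0, swing=5.0),
                       FS, 60.0, seed=1)
        assert np.median(sig.samples) == pytest.approx(8.0, abs=0.5)

    def test_spectral_fundamental_at_breathing_rate(self):
        rr = 18.0
        sig = gen_peso(BreathSpec(mode="active", rr=rr, swing=8.0), FS, 60.0, seed=1)
        x = sig.samples - sig.samples.mean()
        amp = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(x.size, 1 / FS)
        assert freqs[np.argmax(amp)] == pytest.approx(rr / 60.0, abs=1.0 / 60.0)

    def test_band_discipline_little_energy_in_cardiac_band(self):
        # the cardiac band must stay free for the CGO: a premise of the method
        sig = gen_peso(BreathSpec(mode="active", rr=30, swing=10.0), FS, 60.0, seed=3)
        x = sig.samples - sig.samples.mean()
        amp2 = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(x.size, 1 / FS)
        assert amp2[freqs >= 0.8].sum() / amp2.sum() < 0.01

    def test_rr_outside_envelope_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gen_peso(BreathSpec(rr=45.0), FS, 60.0, seed=1)

    def test_deterministic_per_seed(self):
        a = gen_peso(BreathSpec(), FS, 30.0, seed=9)
        b = gen_peso(BreathSpec(), FS, 30.0, seed=9)
        c = gen_peso(BreathSpec(), FS, 30.0, seed=10)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_normalize_scales_to_unit_peak(self):
        sig = gen_peso(BreathSpec(normalize=True, swing=12.0), FS, 30.0, seed=2)
        assert np.max(np.abs(sig.samples)) == pytest.approx(1.0)


class TestGenCgo:
    def test_single_harmonic_is_pure_sinusoid(self):
        spec = CgoSpec(heart_rate=1.0, n_harmonics=1, am_depth=0.0)
        sig = gen_cgo(spec, FS, 20.0, seed=1)
        t = np.arange(len(sig)) / FS
        # fit amplitude/phase at 1 Hz; residual should vanish
        design = np.column_stack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)])
        resid = sig.samples - design @ np.linalg.lstsq(design, sig.samples, rcond=None)[0]
        assert np.max(np.abs(resid)) < 1e-8

    def test_fundamental_recovered_cross_module(self):
        sig = gen_cgo(CgoSpec(heart_rate=1.3), FS, 60.0, seed=4)
        assert abs(estimate_fcgo(sig).f_cgo - 1.3) <= FS / len(sig)

    def test_zero_mean(self):
        sig = gen_cgo(CgoSpec(), FS, 30.0, seed=5)
        assert abs(sig.samples.mean()) < 1e-10 * np.max(np.abs(sig.samples))

    def test_heart_rate_band_enforced(self):
        with pytest.raises(InvalidArgumentError):
            gen_cgo(CgoSpec(heart_rate=0.5), FS, 30.0, seed=1)

    def test_harmonics_above_nyquist_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gen_cgo(CgoSpec(heart_rate=3.0, n_harmonics=20), FS, 30.0, seed=1)


class TestMix:
    def test_zero_factor_is_identity(self):
        peso = gen_peso(BreathSpec(), FS, 30.0, seed=1)
        cgo = gen_cgo(CgoSpec(), FS, 30.0, seed=2)
        np.testing.assert_array_equal(mix(peso, cgo, 0.0).samples, peso.samples)

    def test_added_term_peak_is_f_times_peso_peak(self):
        peso = gen_peso(BreathSpec(swing=10.0), FS, 30.0, seed=1)
        cgo = gen_cgo(CgoSpec(), FS, 30.0, seed=2)
        for f in (0.5, 1.0):
            added = mix(peso, cgo, f).samples - peso.samples
            expected = f * np.max(np.abs(peso.samples))
            assert np.max(np.abs(added)) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(min_value=0.01, max_value=1.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_residual_reproduces_normalized_cgo(self, f):
        peso = gen_peso(BreathSpec(), FS, 30.0, seed=3)
        cgo = gen_cgo(CgoSpec(), FS, 30.0, seed=4)
        residual = mix(peso, cgo, f).samples - peso.samples
        unit = cgo.samples / np.max(np.abs(cgo.samples))
        np.testing.assert_allclose(
            residual / (f * np.max(np.abs(peso.samples))), unit, atol=1e-12)

    def test_length_mismatch_rejected(self):
        peso = gen_peso(BreathSpec(), FS, 30.0, seed=1)
        cgo = gen_cgo(CgoSpec(), FS, 20.0, seed=2)
        with pytest.raises(InvalidArgumentError):
            mix(peso, cgo, 0.5)


class TestAddWgn:
    def test_none_sentinel_is_identity(self):
        sig = gen_peso(BreathSpec(), FS, 30.0, seed=1)
        assert add_wgn(sig, None, seed=1) is sig

    @pytest.mark.parametrize("target_db", [0.0, 10.0, 20.0])
    def test_realized_snr_within_tenth_db(self, target_db):
        sig = gen_peso(BreathSpec(), FS, 60.0, seed=1)
        noisy = add_wgn(sig, target_db, seed=2)
        assert snr_db(sig, noisy) == pytest.approx(target_db, abs=0.1)

    def test_same_seed_same_noise(self):
        sig = gen_peso(BreathSpec(), FS, 30.0, seed=1)
        a = add_wgn(sig, 10.0, seed=7)
        b = add_wgn(sig, 10.0, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_zero_power_signal_rejected(self):
        from pesodenoise import PressureSignal
        with pytest.raises(InvalidArgumentError):
            add_wgn(PressureSignal(np.zeros(100), FS), 10.0, seed=1)


def test_bundle_generator_is_deterministic_and_consistent():
    spec = SynthSpec(mix=MixSpec(f=0.4, wgn_snr_db=15.0))
    c1, g1, n1 = gen_synpeso(spec, FS, 30.0, seed=11)
    c2, g2, n2 = gen_synpeso(spec, FS, 30.0, seed=11)
    np.testing.assert_array_equal(n1.samples, n2.samples)
    assert len(c1) == len(g1) == len(n1)
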