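"""Shared fixtures and the seeded study-condition ensemble.

The "study ensemble" mirrors the evaluation conditions used throughout:
active-breathing records at fs=100 Hz, 60 s, respiratory rate drawn
uniformly from 12-35 breaths/min, pressure swing from 5-15 cmH2O, and a
model CGO with heart rate drawn from 0.9-2.5 Hz, mixed at a scaling
factor F. Parameters are drawn deterministically per integer seed.
"""

import numpy as np
import pytest

from pesodenoise import (
    BreathSpec,
    CgoSpec,
    MixSpec,
    PressureSignal,
    SynthSpec,
    gen_synpeso,
)

FS = 100.0
DURATION = 60.0


def study_record(seed: int, f: float, am_depth: float = 0.0,
                 wgn_snr_db: float | None = None):
    """(clean, cgo, contaminated) under the study conditions for one seed."""
    r = np.random.default_rng(seed)
    rr = r.uniform(12.0, 35.0)
    swing = r.uniform(5.0, 15.0)
    heart_rate = r.uniform(0.9, 2.5)
    spec = SynthSpec(
        breath=BreathSpec(mode="active", rr=rr, swing=swing),
        cgo=CgoSpec(heart_rate=heart_rate, am_depth=am_depth),
        mix=MixSpec(f=f, wgn_snr_db=wgn_snr_db),
    )
    clean, cgo, noisy = gen_synpeso(spec, FS, DURATION, seed)
    return clean, cgo, noisy, {"rr": rr, "swing": swing, "heart_rate": heart_rate}


@pytest.fixture(scope="session")
def sinusoid():
    """1 Hz unit sinusoid, fs=50 Hz, 30 s."""
    fs = 50.0
    t = np.arange(int(30 * fs)) / fs
    return PressureSignal(np.sin(2 * np.pi * 1.0 * t), fs)


@pytest.fixture(scope="session")
def study_f03():
    """Twenty seeded study records at F=0.3 (the headline ensemble)."""
    return [study_record(seed, f=0.3) for seed in range(1, 21)]
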