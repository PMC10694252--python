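import numpy as np
import pytest

from vocrecall import (
    AudioSignal,
    Proposition,
    PropositionBank,
    assign_levels,
    make_synthetic_passages,
)

RATE = 22050.0  # analysis range 80-8000 Hz fits comfortably under Nyquist


@pytest.fixture(scope="session")
def speech_like() -> AudioSignal:
    """Speech-shaped test signal: formant-band noise with slow AM.

    Three noise bands weighted like a long-term speech spectrum (strong
    low-formant region, weaker high frequencies), amplitude-modulated at
    a syllable-like 4 Hz. Not speech, but has the spectral shape and
    temporal envelope structure the vocoder is designed around.
    """
    from scipy import signal as sps

    rng = np.random.default_rng(42)
    n = int(1.5 * RATE)

    def band_noise(lo, hi, weight):
        sos = sps.butter(2, [lo, hi], btype="bandpass", fs=RATE, output="sos")
        return weight * sps.sosfilt(sos, rng.standard_normal(n))

    sig = band_noise(250, 800, 1.0) + band_noise(800, 2500, 0.5) + band_noise(2500, 7000, 0.2)
    t = np.arange(n) / RATE
    am = 1.0 + 0.8 * np.sin(2 * np.pi * 4.0 * t)
    return AudioSignal(sig * am, RATE)


@pytest.fixture(scope="session")
def toy_bank() -> PropositionBank:
    """Six propositions, two per level, about making and flying a kite."""
    props = [
        Proposition("P1", "make", ("kite",)),
        Proposition("P2", "fly", ("kite",)),
        Proposition("P3", "need", ("P1", "paper")),
        Proposition("P4", "help", ("P2", "wind")),
        Proposition("P5", "bright", ("paper",)),
        Proposition("P6", "strong", ("P5", "string")),
    ]
    bank = PropositionBank(
        "kite", props, root_ids=["P1", "P2"], synonyms={"bright": {"colorful"}}
    )
    return assign_levels(bank)


@pytest.fixture(scope="session")
def passages():
    return make_synthetic_passages()
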