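"""Mono audio container and WAV I/O.

The :class:`AudioSignal` is the unit of all signal processing in this
package: a finite real-valued sample vector with its sampling rate.
Amplitudes are dimensionless; WAV files are read into float64 regardless
of on-disk encoding (PCM16 is scaled to [-1, 1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile


@dataclass(frozen=True)
class AudioSignal:
    """A mono sampled waveform.

    Parameters
    ----------
    samples
        Finite real amplitudes, length >= 1.
    rate_hz
        Sampling rate in samples per second, > 0. Default 44100, the rate
        of the study recordings this package models.
    """

    samples: np.ndarray
    rate_hz: float = 44100.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D (mono), got shape {samples.shape}")
        if samples.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must all be finite")
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def nyquist_hz(self) -> float:
        return self.rate_hz / 2.0

    def rms(self) -> float:
        """Root-mean-square amplitude."""
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def with_samples(self, samples: np.ndarray) -> "AudioSignal":
        """A copy of this signal with new samples at the same rate."""
        return AudioSignal(samples, self.rate_hz)


def read_wav(path) -> AudioSignal:
    """Read a mono WAV file (PCM 16-bit or float32) as an AudioSignal.

    PCM16 samples are scaled by 2**15 so full scale maps to [-1, 1).
    Stereo and other multi-channel files are rejected.
    """
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels; "
            "downmix before processing"
        )
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return AudioSignal(samples, float(rate))


def write_wav(path, signal: AudioSignal, subtype: str = "float32") -> None:
    """Write an AudioSignal to WAV as float32 (default) or 16-bit PCM.

    For ``pcm16`` output samples are clipped to [-1, 1] first.
    """
    if subtype == "float32":
        wavfile.write(path, int(round(signal.rate_hz)), signal.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(signal.samples, -1.0, 1.0)
        wavfile.write(
            path,
            int(round(signal.rate_hz)),
            np.round(clipped * 32767.0).astype(np.int16),
        )
    else:
        raise ValueError(f"unsupported subtype {subtype!r} (use 'float32' or 'pcm16')")
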