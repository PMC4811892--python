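"""Mono audio container and WAV I/O.

All DSP in the package operates on :class:`AudioSignal`: a float array of
amplitude samples (nominal range -1..1) at a fixed sample rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile


@dataclass(frozen=True)
class AudioSignal:
    """Mono audio: amplitude samples at ``rate`` Hz."""

    samples: np.ndarray
    rate: int
    __slots__ = ("samples", "rate")

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("AudioSignal requires a 1-D (mono) sample array")
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioSignal samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(len(self.samples)) / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples)))) if len(self) else 0.0


def read_wav(path) -> AudioSignal:
    """Read a mono WAV file (PCM 16/32-bit or float32/64) to floats in -1..1."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype.kind == "i":
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    elif data.dtype.kind == "u":  # 8-bit PCM is unsigned
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    return AudioSignal(data, int(rate))


def write_wav(path, signal: AudioSignal, subtype: str = "float32") -> None:
    """Write a mono WAV file; ``subtype`` is ``float32`` or ``pcm16``."""
    if subtype == "float32":
        wavfile.write(path, signal.rate, signal.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(signal.samples, -1.0, 1.0)
        wavfile.write(path, signal.rate, np.round(clipped * 32767.0).astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV subtype {subtype!r}")
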