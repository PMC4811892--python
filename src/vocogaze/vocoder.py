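"""Acoustic cochlear-implant simulation: an eight-channel sinewave vocoder.

The input signal (100 Hz - 10 kHz by default) is split into ``n_channels``
band-pass channels whose edges are equally spaced along the basilar membrane
according to Greenwood's frequency-position map.  Each channel's amplitude
envelope is extracted by half-wave rectification followed by a low-pass
Butterworth filter, and the output is resynthesised as a sum of sinusoids at
the channel centre frequencies, each modulated by its channel envelope.  This
discards spectrotemporal fine structure while preserving per-band temporal
envelopes - and, crucially for durational-cue studies, the exact sample count
of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .audio import AudioSignal

__all__ = [
    "GreenwoodMap",
    "VocoderConfig",
    "Filterbank",
    "greenwood_frequency",
    "greenwood_position",
    "design_filterbank",
    "bandpass",
    "extract_envelope",
    "vocode",
]


@dataclass(frozen=True)
class GreenwoodMap:
    """Greenwood frequency-position map ``F(x) = A * (10**(a*x) - k)``.

    ``x`` is relative position along the basilar membrane in [0, 1]
    (apex -> base).  Defaults are the conventional human parameterisation.
    """

    A: float = 165.4
    a: float = 2.1
    k: float = 0.88

    def __post_init__(self) -> None:
        if self.A <= 0 or self.a <= 0:
            raise ValueError("GreenwoodMap requires A > 0 and a > 0")


def greenwood_frequency(x, gmap: GreenwoodMap = GreenwoodMap()):
    """Characteristic frequency (Hz) at relative cochlear position ``x`` in [0, 1]."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("relative cochlear position must lie in [0, 1]")
    f = gmap.A * (10.0 ** (gmap.a * x) - gmap.k)
    return float(f) if f.ndim == 0 else f


def greenwood_position(f, gmap: GreenwoodMap = GreenwoodMap()):
    """Inverse of :func:`greenwood_frequency`: relative position for ``f`` Hz."""
    f = np.asarray(f, dtype=np.float64)
    arg = f / gmap.A + gmap.k
    if np.any(arg <= 0):
        raise ValueError("frequency out of the Greenwood map's domain (f/A + k <= 0)")
    x = np.log10(arg) / gmap.a
    return float(x) if x.ndim == 0 else x


@dataclass(frozen=True)
class VocoderConfig:
    """Vocoder settings.

    ``center_mode`` picks how channel centre frequencies are derived from the
    band edges: ``"greenwood"`` (midpoint in cochlear position, the default,
    consistent with place-based spacing), ``"geometric"`` or ``"arithmetic"``.
    ``band_order`` is the order of the band-split Butterworth filters;
    ``zero_phase`` applies every filter forward-backward so that splice timing
    is not shifted.
    """

    n_channels: int = 8
    f_lo: float = 100.0
    f_hi: float = 10_000.0
    env_cutoff: float = 300.0
    env_order: int = 4
    carrier: str = "sinusoid"
    band_order: int = 4
    center_mode: str = "greenwood"
    zero_phase: bool = True
    gmap: GreenwoodMap = field(default_factory=GreenwoodMap)

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError("require 0 < f_lo < f_hi")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.env_cutoff <= 0 or self.env_order < 1 or self.band_order < 1:
            raise ValueError("invalid envelope/band filter settings")
        if self.carrier != "sinusoid":
            raise ValueError("only sinusoid carriers are supported")
        if self.center_mode not in ("greenwood", "geometric", "arithmetic"):
            raise ValueError(f"unknown center_mode {self.center_mode!r}")


@dataclass(frozen=True)
class Filterbank:
    """Band edges (n+1) and centre frequencies (n), all in Hz, increasing."""

    edges: np.ndarray
    centers: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.float64)
        centers = np.asarray(self.centers, dtype=np.float64)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "centers", centers)
        if len(edges) != len(centers) + 1:
            raise ValueError("need exactly one more edge than centers")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("band edges must be strictly increasing")
        if np.any(centers <= edges[:-1]) or np.any(centers >= edges[1:]):
            raise ValueError("each center must lie strictly inside its band")

    @property
    def n_channels(self) -> int:
        return len(self.centers)


def design_filterbank(config: VocoderConfig) -> Filterbank:
    """Bands equally spaced in basilar-membrane position between f_lo and f_hi."""
    gmap = config.gmap
    x_lo = greenwood_position(config.f_lo, gmap)
    x_hi = greenwood_position(config.f_hi, gmap)
    x_edges = np.linspace(x_lo, x_hi, config.n_channels + 1)
    edges = greenwood_frequency(x_edges, gmap)
    # pin the endpoints exactly (linspace + round trip is exact to ~1e-12 anyway)
    edges[0], edges[-1] = config.f_lo, config.f_hi
    if config.center_mode == "greenwood":
        centers = greenwood_frequency((x_edges[:-1] + x_edges[1:]) / 2.0, gmap)
    elif config.center_mode == "geometric":
        centers = np.sqrt(edges[:-1] * edges[1:])
    else:
        centers = (edges[:-1] + edges[1:]) / 2.0
    return Filterbank(np.atleast_1d(edges), np.atleast_1d(centers))


def _apply_sos(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        padlen = 3 * (2 * sos.shape[0] + 1)
        if len(x) <= padlen:
            raise ValueError(
                f"signal too short for filter warm-up: need > {padlen} samples, got {len(x)}"
            )
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def bandpass(
    signal: AudioSignal,
    lo: float,
    hi: float,
    order: int = 4,
    zero_phase: bool = True,
) -> AudioSignal:
    """Butterworth band-pass, zero-phase by default; length preserved."""
    nyq = signal.rate / 2.0
    if not (0 < lo < hi):
        raise ValueError("require 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"upper edge {hi} Hz reaches Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=signal.rate, output="sos")
    return AudioSignal(_apply_sos(sos, signal.samples, zero_phase), signal.rate)


def extract_envelope(
    band: AudioSignal,
    cutoff: float = 300.0,
    order: int = 4,
    zero_phase: bool = True,
) -> AudioSignal:
    """Amplitude envelope: half-wave rectification then low-pass Butterworth.

    The low-pass stage has unit DC gain, so a stationary unit-amplitude tone
    yields an envelope whose mean is the rectified sine's DC term 1/pi.
    """
    if cutoff >= band.rate / 2.0:
        raise ValueError("envelope cutoff must be below Nyquist")
    rectified = np.maximum(band.samples, 0.0)
    sos = sps.butter(order, cutoff, btype="lowpass", fs=band.rate, output="sos")
    return AudioSignal(_apply_sos(sos, rectified, zero_phase), band.rate)


def vocode(signal: AudioSignal, config: VocoderConfig = VocoderConfig()) -> AudioSignal:
    """Sinewave-vocode ``signal``; output length and rate equal the input's."""
    if signal.rate < 2 * config.f_hi:
        raise ValueError(
            f"sample rate {signal.rate} Hz too low for f_hi={config.f_hi} Hz; "
            "resample the input first (automatic resampling is deliberately not done)"
        )
    bank = design_filterbank(config)
    t = signal.times
    out = np.zeros(len(signal))
    for lo, hi, fc in zip(bank.edges[:-1], bank.edges[1:], bank.centers):
        band = bandpass(signal, lo, hi, config.band_order, config.zero_phase)
        env = extract_envelope(band, config.env_cutoff, config.env_order, config.zero_phase)
        # carrier phase 0 at signal start: deterministic resynthesis
        out += env.samples * np.sin(2.0 * np.pi * fc * t)
    return AudioSignal(out, signal.rate)
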