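"""Stimulus construction: cross-splicing and a synthetic stimulus inventory.

The experimental materials pair a polysyllabic target word (e.g. Dutch
*bokser*) with a monosyllabic competitor embedded in its first syllable
(*bok*).  Because of pre-boundary lengthening the standalone monosyllable is
longer than the same syllable inside the polysyllabic word, by 20-120 ms
(mean 65 ms) in the original materials.  Two conditions are built by
cross-splicing:

* Condition 1 (target-matching duration cues): first part of one recording of
  the polysyllabic sentence + second part of a second recording of the same
  sentence.
* Condition 2 (target-mismatching cues): first part of the monosyllabic
  sentence (longer first syllable) + the same polysyllabic second part.

No natural recordings ship with the package; :func:`synthesize_token` builds
harmonic-complex stand-ins with a marked splice boundary, and
:func:`generate_stimulus_inventory` draws a full 26-pair + 40-filler
inventory whose duration-difference statistics emulate the materials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import AudioSignal
from .vocoder import VocoderConfig, vocode

__all__ = [
    "SentenceToken",
    "StimulusPair",
    "ConditionStimulus",
    "cross_splice",
    "synthesize_token",
    "build_condition_stimuli",
    "generate_stimulus_inventory",
    "inventory_manifest",
]

#: Duration-difference model: 20 + 100 * Beta(alpha, beta) ms.  With the
#: default alpha/beta the mean is 20 + 100 * 2.25/5 = 65 ms, matching the
#: original materials' mean; a uniform draw on [20, 120] would force 70 ms.
DIFF_RANGE_MS = (20.0, 120.0)
DIFF_BETA_ALPHA = 2.25
DIFF_BETA_BETA = 2.75


@dataclass(frozen=True)
class SentenceToken:
    """A (synthetic) sentence recording with a marked splice boundary.

    ``boundary_ms`` marks the end of the first syllable of the polysyllabic
    word, or the end of the monosyllabic word, depending on ``label``.
    """

    audio: AudioSignal
    boundary_ms: float
    label: str = "poly_recording_1"

    def __post_init__(self) -> None:
        if not (0 < self.boundary_ms < self.audio.duration_ms):
            raise ValueError(
                f"boundary {self.boundary_ms} ms outside (0, {self.audio.duration_ms}) ms"
            )
        if self.label not in ("poly_recording_1", "poly_recording_2", "mono_recording"):
            raise ValueError(f"unknown token label {self.label!r}")

    @property
    def boundary_sample(self) -> int:
        return int(round(self.boundary_ms * self.audio.rate / 1000.0))


@dataclass(frozen=True)
class StimulusPair:
    pair_id: int
    syllable_duration_poly_ms: float
    syllable_duration_mono_ms: float

    @property
    def duration_difference_ms(self) -> float:
        return self.syllable_duration_mono_ms - self.syllable_duration_poly_ms

    def __post_init__(self) -> None:
        if self.duration_difference_ms <= 0:
            raise ValueError(
                "pre-boundary lengthening makes the monosyllable longer: "
                f"difference {self.duration_difference_ms} ms must be > 0"
            )


@dataclass(frozen=True)
class FillerItem:
    filler_id: int
    syllabic_type: str  # "polysyllabic" | "monosyllabic"
    embedding: str  # "none" | "initial" | "final"
    word_duration_ms: float


@dataclass(frozen=True)
class Inventory:
    pairs: tuple
    fillers: tuple
    seed: int | None = None

    @property
    def n_critical(self) -> int:
        return len(self.pairs)

    @property
    def n_filler(self) -> int:
        return len(self.fillers)


@dataclass(frozen=True)
class ConditionStimulus:
    condition: str  # "target_matching" | "target_mismatching" | "filler"
    audio: AudioSignal
    presentation: str = "NS"  # "NS" natural | "DS" degraded (vocoded)

    def __post_init__(self) -> None:
        if self.condition not in ("target_matching", "target_mismatching", "filler"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.presentation not in ("NS", "DS"):
            raise ValueError(f"unknown presentation {self.presentation!r}")


def _snap_to_zero_crossing(samples: np.ndarray, idx: int, max_shift: int) -> int:
    """Nearest index to ``idx`` where the waveform crosses zero (sign change)."""
    lo = max(1, idx - max_shift)
    hi = min(len(samples) - 1, idx + max_shift)
    if hi <= lo:
        return idx
    seg = samples[lo - 1 : hi + 1]
    crossings = np.nonzero(np.signbit(seg[:-1]) != np.signbit(seg[1:]))[0] + lo
    if len(crossings) == 0:
        return idx
    return int(crossings[np.argmin(np.abs(crossings - idx))])


def cross_splice(
    part1: SentenceToken,
    part2: SentenceToken,
    snap_zero_crossing: bool = True,
    max_snap_ms: float = 5.0,
) -> AudioSignal:
    """Concatenate part1 up to its boundary with part2 from its boundary on.

    Sample-exact concatenation: no resampling or windowing, so the durational
    cue carried by the first part survives untouched.  Optionally each cut
    point is snapped to the nearest zero crossing (within ``max_snap_ms``) to
    avoid splice clicks.
    """
    if part1.audio.rate != part2.audio.rate:
        raise ValueError(
            f"sample-rate mismatch: {part1.audio.rate} vs {part2.audio.rate} Hz"
        )
    rate = part1.audio.rate
    i1, i2 = part1.boundary_sample, part2.boundary_sample
    if snap_zero_crossing:
        max_shift = int(round(max_snap_ms * rate / 1000.0))
        i1 = _snap_to_zero_crossing(part1.audio.samples, i1, max_shift)
        i2 = _snap_to_zero_crossing(part2.audio.samples, i2, max_shift)
    spliced = np.concatenate([part1.audio.samples[:i1], part2.audio.samples[i2:]])
    return AudioSignal(spliced, rate)


def synthesize_token(
    duration_ms: float,
    f0: float = 150.0,
    spectral_tilt_db_oct: float = -6.0,
    boundary_ms: float | None = None,
    rate: int = 44_100,
    seed: int | None = None,
    label: str = "poly_recording_1",
) -> SentenceToken:
    """Synthetic harmonic-complex stand-in for a recorded sentence.

    A harmonic complex at ``f0`` with a spectral tilt, a slow random amplitude
    contour (speech-like 3-5 Hz modulation) and raised-cosine onset/offset
    ramps.  Deterministic given ``seed``.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms * rate / 1000.0))
    t = np.arange(n) / rate
    nyq = rate / 2.0
    n_harm = max(1, int(min(5000.0, nyq * 0.9) // f0))
    tone = np.zeros(n)
    for h in range(1, n_harm + 1):
        amp = 10.0 ** (spectral_tilt_db_oct * np.log2(h) / 20.0)
        tone += amp * np.sin(2.0 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi))
    # slow syllabic amplitude modulation
    mod_rate = rng.uniform(3.0, 5.0)
    contour = 0.7 + 0.3 * np.sin(2.0 * np.pi * mod_rate * t + rng.uniform(0, 2 * np.pi))
    ramp_n = min(n // 10, int(0.01 * rate))
    window = np.ones(n)
    if ramp_n > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        window[:ramp_n] = ramp
        window[-ramp_n:] = ramp[::-1]
    samples = tone * contour * window
    samples /= max(1e-12, np.max(np.abs(samples))) / 0.5
    if boundary_ms is None:
        boundary_ms = duration_ms / 2.0
    return SentenceToken(AudioSignal(samples, rate), boundary_ms, label)


def draw_duration_differences(n: int, rng: np.random.Generator) -> np.ndarray:
    """Duration differences in ms: scaled Beta on [20, 120] with mean 65."""
    lo, hi = DIFF_RANGE_MS
    return lo + (hi - lo) * rng.beta(DIFF_BETA_ALPHA, DIFF_BETA_BETA, size=n)


def generate_stimulus_inventory(
    n_critical: int = 26,
    n_filler: int = 40,
    filler_polysyllabic: int = 7,
    filler_monosyllabic: int = 33,
    filler_no_competitor: int = 20,
    filler_initial_embedding: int = 10,
    filler_final_embedding: int = 10,
    seed: int | None = None,
) -> Inventory:
    """Draw the default synthetic inventory: 26 critical pairs + 40 fillers.

    Critical pairs get first-syllable durations for the polysyllabic token
    and a longer monosyllabic token whose excess duration follows the scaled
    Beta model (support [20, 120] ms, mean 65 ms).  Fillers are partitioned
    7 polysyllabic / 33 monosyllabic and, by competitor structure, 20 without
    competitor, 10 with initial and 10 with final embedding.
    """
    if n_critical < 0 or n_filler < 0:
        raise ValueError("counts must be >= 0")
    if filler_polysyllabic + filler_monosyllabic != n_filler:
        raise ValueError("syllabic filler partition does not sum to n_filler")
    if filler_no_competitor + filler_initial_embedding + filler_final_embedding != n_filler:
        raise ValueError("competitor filler partition does not sum to n_filler")
    rng = np.random.default_rng(seed)
    poly_syll = rng.uniform(160.0, 260.0, size=n_critical)
    diffs = draw_duration_differences(n_critical, rng)
    pairs = tuple(
        StimulusPair(i, float(p), float(p + d))
        for i, (p, d) in enumerate(zip(poly_syll, diffs))
    )
    syllabic = ["polysyllabic"] * filler_polysyllabic + ["monosyllabic"] * filler_monosyllabic
    embedding = (
        ["none"] * filler_no_competitor
        + ["initial"] * filler_initial_embedding
        + ["final"] * filler_final_embedding
    )
    rng.shuffle(embedding)
    fillers = tuple(
        FillerItem(j, s, e, float(rng.uniform(250.0, 700.0)))
        for j, (s, e) in enumerate(zip(syllabic, embedding))
    )
    return Inventory(pairs, fillers, seed)


def build_condition_stimuli(
    pair: StimulusPair,
    rate: int = 44_100,
    sentence_tail_ms: float = 600.0,
    sentence_lead_ms: float = 800.0,
    seed: int | None = None,
    vocoder_config: VocoderConfig | None = None,
) -> dict:
    """Render both spliced conditions for one critical pair, NS and DS.

    Three tokens are synthesised per pair (two 'recordings' of the
    polysyllabic sentence, one of the monosyllabic sentence); the boundary
    falls at sentence_lead + first-syllable duration.  Returns a dict keyed
    by (condition, presentation).
    """
    base = 0 if seed is None else seed
    dur_poly = sentence_lead_ms + pair.syllable_duration_poly_ms + sentence_tail_ms
    dur_mono = sentence_lead_ms + pair.syllable_duration_mono_ms + sentence_tail_ms
    poly1 = synthesize_token(
        dur_poly, boundary_ms=sentence_lead_ms + pair.syllable_duration_poly_ms,
        rate=rate, seed=base * 3 + 0, label="poly_recording_1")
    poly2 = synthesize_token(
        dur_poly, boundary_ms=sentence_lead_ms + pair.syllable_duration_poly_ms,
        rate=rate, seed=base * 3 + 1, label="poly_recording_2")
    mono = synthesize_token(
        dur_mono, boundary_ms=sentence_lead_ms + pair.syllable_duration_mono_ms,
        rate=rate, seed=base * 3 + 2, label="mono_recording")
    cond1 = cross_splice(poly1, poly2)
    cond2 = cross_splice(mono, poly2)
    cfg = vocoder_config or VocoderConfig()
    out = {
        ("target_matching", "NS"): ConditionStimulus("target_matching", cond1, "NS"),
        ("target_mismatching", "NS"): ConditionStimulus("target_mismatching", cond2, "NS"),
        ("target_matching", "DS"): ConditionStimulus(
            "target_matching", vocode(cond1, cfg), "DS"),
        ("target_mismatching", "DS"): ConditionStimulus(
            "target_mismatching", vocode(cond2, cfg), "DS"),
    }
    return out


def inventory_manifest(inventory: Inventory) -> pd.DataFrame:
    """Tidy manifest of the inventory (one row per critical pair or filler)."""
    rows = [
        {
            "item_id": f"crit{p.pair_id:03d}",
            "item_type": "critical",
            "syllable_duration_poly_ms": p.syllable_duration_poly_ms,
            "syllable_duration_mono_ms": p.syllable_duration_mono_ms,
            "duration_difference_ms": p.duration_difference_ms,
            "embedding": "initial",
        }
        for p in inventory.pairs
    ] + [
        {
            "item_id": f"fill{f.filler_id:03d}",
            "item_type": f"filler_{f.syllabic_type}",
            "syllable_duration_poly_ms": np.nan,
            "syllable_duration_mono_ms": np.nan,
            "duration_difference_ms": np.nan,
            "embedding": f.embedding,
        }
        for f in inventory.fillers
    ]
    return pd.DataFrame(rows)
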