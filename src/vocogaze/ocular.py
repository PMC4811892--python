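"""Ocular-trace preprocessing: blinks, screening, baselines and %ERPD.

Raw traces are 250-Hz samples of gaze position and pupil area with a validity
flag.  The tracker records blinks as invalid samples (zero pupil).  The
cleaning rules:

* blinks shorter than 300 ms are linearly interpolated between the medians of
  the 25 valid samples before and after the blink;
* trials with a blink of 300 ms or longer, or with an incorrect click, are
  excluded;
* participants whose excluded trials reach 50% of the session are dropped.

Event-related pupil dilation is expressed as percent change from a baseline:

    %ERPD = (observation - baseline) / baseline * 100

with baseline 1 the mean pupil area in the 200 ms preceding the target word
(per trial) and baseline 2 the mean pupil area in the 200 ms preceding the
very first sentence of the session (per participant).  All windows are
half-open ``[start, end)`` with 0-based sample indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "OcularTrace",
    "TrialRecord",
    "BlinkEvent",
    "Epoch",
    "ScreenResult",
    "detect_blinks",
    "interpolate_blink",
    "screen_trial",
    "screen_participant",
    "compute_baseline",
    "erpd",
    "epoch",
    "count_fixations",
    "read_trace_tsv",
    "write_trace_tsv",
    "read_trials_tsv",
    "write_trials_tsv",
]

DEFAULT_RATE = 250
BLINK_MAX_MS = 300.0
BASELINE_MS = 200.0
ANALYSIS_WINDOW_MS = (200.0, 2000.0)
FIXATION_GCA_WINDOW_MS = (200.0, 1800.0)
MIN_FIXATION_MS = 80.0
INTERP_CONTEXT_SAMPLES = 25


class InsufficientContextError(ValueError):
    """Raised when a blink lacks 25 valid context samples on a side."""


@dataclass(frozen=True)
class OcularTrace:
    """Sample-level ocular recording at a constant rate (default 250 Hz)."""

    t: np.ndarray  # ms since session start
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray  # pupil area, device units; 0 where invalid
    valid: np.ndarray  # bool
    rate: float = DEFAULT_RATE

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "pupil"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))
        n = len(self.t)
        if any(len(getattr(self, f)) != n for f in ("x", "y", "pupil", "valid")):
            raise ValueError("all trace columns must have equal length")
        step = 1000.0 / self.rate
        if n > 1 and not np.allclose(np.diff(self.t), step, atol=step * 1e-6):
            raise ValueError("trace times must increase with constant step 1000/rate")
        if np.any(self.pupil[self.valid] < 0):
            raise ValueError("pupil area must be >= 0 where valid")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def step_ms(self) -> float:
        return 1000.0 / self.rate

    def index_at(self, t_ms: float) -> int:
        """Index of the first sample with t >= t_ms."""
        return int(np.searchsorted(self.t, t_ms - 1e-9))

    def window(self, t0: float, t1: float) -> slice:
        """Slice covering samples with t in [t0, t1)."""
        return slice(self.index_at(t0), self.index_at(t1))


@dataclass(frozen=True)
class TrialRecord:
    trial_id: int
    condition: str  # target_matching | target_mismatching | filler
    presentation: str  # NS | DS
    sentence_onset_ms: float
    target_word_onset_ms: float
    clicked_role: str  # target | competitor | distractor_a | distractor_b
    correct: bool

    def __post_init__(self) -> None:
        if self.sentence_onset_ms >= self.target_word_onset_ms:
            raise ValueError("sentence onset must precede target word onset")


@dataclass(frozen=True)
class BlinkEvent:
    start_ms: float
    end_ms: float
    start_idx: int
    end_idx: int  # exclusive

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("blink duration must be positive")


@dataclass(frozen=True)
class Epoch:
    """Trial-locked samples, time relative to target-word onset."""

    time_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray
    rate: float
    trial_id: int = -1
    condition: str = ""
    presentation: str = ""
    participant: str = ""

    def __len__(self) -> int:
        return len(self.time_ms)


@dataclass(frozen=True)
class ScreenResult:
    keep: bool
    reason: str | None = None
    trace: OcularTrace | None = None  # blink-repaired trace when kept


def detect_blinks(trace: OcularTrace) -> list[BlinkEvent]:
    """Maximal runs of invalid or zero-pupil samples, in time order.

    ``end_ms`` is exclusive (start of the first valid sample after the run),
    so a 50-sample gap at 250 Hz has duration exactly 200 ms.
    """
    bad = (~trace.valid) | (trace.pupil <= 0)
    if not bad.any():
        return []
    padded = np.concatenate([[False], bad, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]  # exclusive
    step = trace.step_ms
    return [
        BlinkEvent(trace.t[s], trace.t[e - 1] + step, int(s), int(e))
        for s, e in zip(starts, ends)
    ]


def interpolate_blink(
    trace: OcularTrace,
    event: BlinkEvent,
    window_samples: int = INTERP_CONTEXT_SAMPLES,
) -> OcularTrace:
    """Repair one blink: linear ramp between robust (median) anchors.

    The anchors are the medians of the ``window_samples`` valid samples
    immediately before and after the gap; only gap samples are touched.
    Gaze x/y are repaired the same way so downstream AOI labelling sees no
    hole.  Raises :class:`InsufficientContextError` when either side lacks
    enough valid context.
    """
    bad = (~trace.valid) | (trace.pupil <= 0)
    pre_idx = np.nonzero(~bad[: event.start_idx])[0][-window_samples:]
    post_rel = np.nonzero(~bad[event.end_idx :])[0][:window_samples]
    if len(pre_idx) < window_samples or len(post_rel) < window_samples:
        raise InsufficientContextError(
            f"blink at {event.start_ms:.0f} ms lacks {window_samples} valid "
            "context samples on one side"
        )
    post_idx = post_rel + event.end_idx
    gap = np.arange(event.start_idx, event.end_idx)
    # interpolate between anchor positions one sample outside the gap
    t0, t1 = trace.t[event.start_idx - 1], trace.t[event.end_idx]
    frac = (trace.t[gap] - t0) / (t1 - t0)
    new_cols = {}
    for name in ("pupil", "x", "y"):
        col = getattr(trace, name).copy()
        a = float(np.median(col[pre_idx]))
        b = float(np.median(col[post_idx]))
        col[gap] = a + frac * (b - a)
        new_cols[name] = col
    valid = trace.valid.copy()
    valid[gap] = True
    return replace(trace, valid=valid, **new_cols)


def screen_trial(
    trial: TrialRecord,
    trace: OcularTrace,
    blink_max_ms: float = BLINK_MAX_MS,
    window_ms: tuple[float, float] = (-BASELINE_MS, ANALYSIS_WINDOW_MS[1]),
) -> ScreenResult:
    """Keep or exclude one trial; repair its short blinks when kept.

    Exclusion triggers: the click missed the target, or any blink overlapping
    the trial's baseline+analysis window (``window_ms`` relative to target
    word onset) lasted ``blink_max_ms`` or longer.  A blink of exactly 300 ms
    is excluded (the boundary case, unassigned by the verbal rule, is
    resolved conservatively).  Shorter blinks are linearly interpolated; if
    one cannot be repaired the trial is excluded as un-repairable.
    """
    if not trial.correct or trial.clicked_role != "target":
        return ScreenResult(False, "incorrect_click")
    t0 = trial.target_word_onset_ms + window_ms[0]
    t1 = trial.target_word_onset_ms + window_ms[1]
    blinks = [b for b in detect_blinks(trace) if b.end_ms > t0 and b.start_ms < t1]
    long_blinks = [b for b in blinks if b.duration_ms >= blink_max_ms]
    if long_blinks:
        return ScreenResult(False, "long_blink")
    repaired = trace
    for b in blinks:
        try:
            repaired = interpolate_blink(repaired, b)
        except InsufficientContextError:
            return ScreenResult(False, "unrepairable_blink")
    return ScreenResult(True, None, repaired)


def screen_participant(results: list[ScreenResult], threshold: float = 0.5) -> bool:
    """True (keep) unless the excluded fraction reaches ``threshold``."""
    if not results:
        return True
    excluded = sum(not r.keep for r in results)
    return excluded / len(results) < threshold


def compute_baseline(
    trace: OcularTrace,
    trial: TrialRecord | None = None,
    kind: int = 1,
    first_sentence_onset_ms: float | None = None,
    baseline_ms: float = BASELINE_MS,
) -> float:
    """Mean pupil area over the baseline window.

    kind 1: the 200 ms immediately preceding the trial's target word.
    kind 2: the 200 ms immediately preceding the session's first sentence
    (one value per participant); pass ``first_sentence_onset_ms``.
    """
    if kind == 1:
        if trial is None:
            raise ValueError("baseline 1 needs a trial")
        anchor = trial.target_word_onset_ms
    elif kind == 2:
        if first_sentence_onset_ms is None:
            raise ValueError("baseline 2 needs the first sentence onset")
        anchor = first_sentence_onset_ms
    else:
        raise ValueError("baseline kind must be 1 or 2")
    sl = trace.window(anchor - baseline_ms, anchor)
    if sl.start < 0 or sl.stop > len(trace) or sl.stop - sl.start == 0:
        raise ValueError("baseline window outside the trace")
    if not trace.valid[sl].all():
        raise ValueError("baseline window overlaps an un-repaired gap")
    return float(np.mean(trace.pupil[sl]))


def erpd(observation, baseline: float):
    """Percent event-related pupil dilation: (obs - baseline)/baseline * 100."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    obs = np.asarray(observation, dtype=np.float64)
    out = (obs - baseline) / baseline * 100.0
    return float(out) if out.ndim == 0 else out


def epoch(
    trace: OcularTrace,
    trial: TrialRecord,
    window_ms: tuple[float, float] = ANALYSIS_WINDOW_MS,
    participant: str = "",
) -> Epoch:
    """Extract [onset+start, onset+end) and re-express time relative to onset.

    At 250 Hz the default 200-2000 ms window yields exactly 450 samples.
    """
    t0 = trial.target_word_onset_ms + window_ms[0]
    t1 = trial.target_word_onset_ms + window_ms[1]
    sl = trace.window(t0, t1)
    n_expected = int(round((window_ms[1] - window_ms[0]) / trace.step_ms))
    if sl.stop - sl.start != n_expected:
        raise ValueError(
            f"trial {trial.trial_id}: epoch truncated "
            f"({sl.stop - sl.start} of {n_expected} samples)"
        )
    return Epoch(
        time_ms=trace.t[sl] - trial.target_word_onset_ms,
        x=trace.x[sl],
        y=trace.y[sl],
        pupil=trace.pupil[sl],
        valid=trace.valid[sl],
        rate=trace.rate,
        trial_id=trial.trial_id,
        condition=trial.condition,
        presentation=trial.presentation,
        participant=participant,
    )


def count_fixations(
    aoi_labels,
    rate: float = DEFAULT_RATE,
    min_duration_ms: float = MIN_FIXATION_MS,
) -> int:
    """Number of maximal same-AOI dwells of at least ``min_duration_ms``.

    Samples labelled None (off-grid) never contribute to a fixation.
    """
    step = 1000.0 / rate
    min_run = max(1, int(np.ceil(min_duration_ms / step)))
    count = 0
    run_label, run_len = None, 0
    for label in list(aoi_labels) + [object()]:  # sentinel flushes last run
        if label == run_label:
            run_len += 1
            continue
        if run_label is not None and run_len >= min_run:
            count += 1
        run_label = label if label is not None else None
        run_len = 1 if label is not None else 0
    return count


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

_TRACE_COLS = ["t_ms", "x", "y", "pupil", "valid"]
_TRIAL_COLS = [
    "trial_id", "condition", "presentation", "sentence_onset_ms",
    "target_word_onset_ms", "clicked_role", "correct",
]


def write_trace_tsv(path, trace: OcularTrace) -> None:
    df = pd.DataFrame({
        "t_ms": trace.t, "x": trace.x, "y": trace.y,
        "pupil": trace.pupil, "valid": trace.valid.astype(int),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_trace_tsv(path, rate: float | None = None) -> OcularTrace:
    df = pd.read_csv(path, sep="\t")
    missing = set(_TRACE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if rate is None:
        steps = np.diff(df["t_ms"].to_numpy())
        rate = 1000.0 / float(np.median(steps))
    return OcularTrace(
        df["t_ms"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy(),
        df["pupil"].to_numpy(), df["valid"].to_numpy().astype(bool), rate,
    )


def write_trials_tsv(path, trials: list[TrialRecord]) -> None:
    df = pd.DataFrame([
        {
            "trial_id": tr.trial_id, "condition": tr.condition,
            "presentation": tr.presentation,
            "sentence_onset_ms": tr.sentence_onset_ms,
            "target_word_onset_ms": tr.target_word_onset_ms,
            "clicked_role": tr.clicked_role, "correct": int(tr.correct),
        }
        for tr in trials
    ])
    df.to_csv(path, sep="\t", index=False)


def read_trials_tsv(path) -> list[TrialRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_TRIAL_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        TrialRecord(
            int(r.trial_id), str(r.condition), str(r.presentation),
            float(r.sentence_onset_ms), float(r.target_word_onset_ms),
            str(r.clicked_role), bool(r.correct),
        )
        for r in df.itertuples()
    ]
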