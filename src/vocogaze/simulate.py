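"""Synthetic session generator with known ground truth.

Generates complete visual-world sessions - 62 trials of which 26 are
critical (13 with target-matching and 13 with target-mismatching duration
cues), 250-Hz gaze/pupil traces, blinks and noise - from an explicit
:class:`GroundTruth` that stores the generating fixation curves and pupil
dilation templates.  Every downstream module is validated against these
known generators.

Fixation ground truth per condition: the target-fixation probability rises
logistically toward an asymptote while the competitor's rises early and
falls after disambiguating information arrives; the target-mismatching
condition is the same pair of curves rigidly delayed by the preset's
crossover offset (120 ms for natural speech, 220 ms for the degraded
preset, whose curves are also shallower).  Gaze is a dwell (fixation)
process: exponential dwell durations whose AOI is drawn from the
ground-truth probabilities at the dwell midpoint; the mean dwell is set so
the 200-2000 ms analysis window contains about three counted fixations.

Pupil ground truth: pupil area = baseline * (1 + template/100), so the
%ERPD formula recovers the stored template exactly on noiseless traces.
The natural-speech template is a gamma-shaped dilation peaking 1000 ms
after word onset (the slow effort response peaks only after 900 ms); the
degraded-speech preset is elevated already before word onset and much
flatter.  AR(1) noise (rho = 0.97 at 250 Hz), a slow random-walk drift and
log-normal blinks are added on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml
from scipy import signal as sps
from scipy.special import expit

from .ocular import (
    ANALYSIS_WINDOW_MS,
    OcularTrace,
    TrialRecord,
    compute_baseline,
    epoch,
    erpd,
    screen_trial,
)
from .fixation import AOILayout, crossover_time, label_epoch, proportion_curves

__all__ = [
    "SessionConfig",
    "GroundTruth",
    "Session",
    "generate_session",
    "simulate_trial_trace",
    "end_to_end_check",
]

ROLE_STATES = ("target", "competitor", "distractor_a", "distractor_b", "center")

# trial geometry (ms relative to target word onset)
SENTENCE_LEAD_MS = 1000.0  # word onset follows sentence onset by this much
TRIAL_TAIL_MS = 2500.0  # trial continues this long after word onset
SESSION_LEAD_MS = 1000.0  # quiet lead-in before the first sentence


@dataclass(frozen=True)
class SessionConfig:
    """Generator settings; defaults are the study's session structure."""

    n_trials: int = 62
    n_critical: int = 26
    n_inventory_fillers: int = 40
    presentation: str = "NS"
    rate: float = 250.0
    baseline_pupil: float = 1000.0
    noise_sd: float = 6.0  # stationary SD of AR(1) pupil noise, device units
    ar_rho: float = 0.97
    drift_sd: float = 8.0  # SD of the slow session drift, device units
    blink_rate: float = 0.15  # expected blinks per trial
    blink_long_frac: float = 0.2  # fraction of blinks drawn from the >300 ms mix
    mean_dwell_ms: float = 300.0  # calibrated: ~3 counted fixations per window
    gaze_jitter_px: float = 20.0
    correct_rate: float = 0.95
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_critical > self.n_trials:
            raise ValueError("n_critical cannot exceed n_trials")
        if not (0 <= self.correct_rate <= 1):
            raise ValueError("correct_rate must be a probability")

    def noiseless(self) -> "SessionConfig":
        """Copy with all stochastic trace components switched off."""
        return replace(self, noise_sd=0.0, drift_sd=0.0, blink_rate=0.0,
                       correct_rate=1.0)


def _logistic(t, m, s):
    return expit((np.asarray(t, dtype=float) - m) / s)


@dataclass(frozen=True)
class GroundTruth:
    """Generating curves for one presentation mode (NS or DS)."""

    presentation: str
    crossover_offset_ms: float
    fixation: dict  # base-curve parameters (see fixation_probs)
    erpd_templates: dict  # condition -> template parameters
    condition_shifts: dict = field(
        default_factory=lambda: {"target_matching": 0.0, "filler": 0.0})

    @classmethod
    def preset(cls, presentation: str = "NS") -> "GroundTruth":
        if presentation == "NS":
            fixation = dict(
                p_base=0.20, target_end=0.85, m_target=850.0, s_target=140.0,
                comp_peak=0.55, comp_rise=350.0, s_rise=110.0,
                comp_decay=800.0, s_decay=150.0, comp_end=0.10,
                filler_m_target=700.0,
            )
            templates = {
                "target_matching": dict(amp=5.0, peak_ms=1000.0, kappa=2.0, pre_amp=0.0),
                "target_mismatching": dict(amp=6.5, peak_ms=1000.0, kappa=2.0, pre_amp=0.0),
                "filler": dict(amp=3.5, peak_ms=1000.0, kappa=2.0, pre_amp=0.0),
            }
            offset = 120.0
        elif presentation == "DS":
            fixation = dict(
                p_base=0.20, target_end=0.80, m_target=950.0, s_target=210.0,
                comp_peak=0.55, comp_rise=330.0, s_rise=150.0,
                comp_decay=900.0, s_decay=220.0, comp_end=0.12,
                filler_m_target=780.0,
            )
            templates = {
                "target_matching": dict(amp=1.5, peak_ms=1300.0, kappa=1.2, pre_amp=6.0),
                "target_mismatching": dict(amp=2.0, peak_ms=1300.0, kappa=1.2, pre_amp=6.0),
                "filler": dict(amp=1.2, peak_ms=1300.0, kappa=1.2, pre_amp=6.0),
            }
            offset = 220.0
        else:
            raise ValueError(f"unknown presentation {presentation!r}")
        shifts = {"target_matching": 0.0, "target_mismatching": offset, "filler": 0.0}
        return cls(presentation, offset, fixation, templates, shifts)

    # -- fixation curves -----------------------------------------------------

    def fixation_probs(self, t_ms, condition: str) -> dict:
        """AOI occupancy probabilities at times ``t_ms`` (rel. word onset)."""
        p = self.fixation
        t = np.asarray(t_ms, dtype=float) - self.condition_shifts[condition]
        if condition == "filler":
            target = p["p_base"] + (p["target_end"] - p["p_base"]) * _logistic(
                t, p["filler_m_target"], p["s_target"])
            comp = p["p_base"] - (p["p_base"] - p["comp_end"]) * _logistic(
                t, p["comp_decay"], p["s_decay"])
        else:
            target = p["p_base"] + (p["target_end"] - p["p_base"]) * _logistic(
                t, p["m_target"], p["s_target"])
            comp = (
                p["p_base"]
                + (p["comp_peak"] - p["p_base"]) * _logistic(t, p["comp_rise"], p["s_rise"])
                - (p["comp_peak"] - p["comp_end"]) * _logistic(t, p["comp_decay"], p["s_decay"])
            )
        rem = np.clip(1.0 - target - comp, 0.0, None)
        return {
            "target": target,
            "competitor": comp,
            "distractor_a": 0.25 * rem,
            "distractor_b": 0.25 * rem,
            "center": 0.5 * rem,
        }

    def true_crossover(self, condition: str, window=ANALYSIS_WINDOW_MS) -> float | None:
        """Crossover of the generating curves themselves (fine 1-ms grid)."""
        t = np.arange(window[0], window[1], 1.0)
        probs = self.fixation_probs(t, condition)
        return crossover_time(t, probs["target"], probs["competitor"])

    # -- pupil template ------------------------------------------------------

    def erpd_template(self, t_ms, condition: str) -> np.ndarray:
        """%ERPD template at times ``t_ms`` relative to word onset."""
        par = self.erpd_templates[condition]
        t = np.asarray(t_ms, dtype=float)
        out = np.zeros_like(t)
        pos = t > 0
        tp, kap = par["peak_ms"], par["kappa"]
        out[pos] = par["amp"] * (t[pos] / tp) ** kap * np.exp(kap * (1.0 - t[pos] / tp))
        if par["pre_amp"]:
            # sustained dilation already present before word onset (degraded mode)
            out += par["pre_amp"] * _logistic(t, -SENTENCE_LEAD_MS + 400.0, 200.0)
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class Session:
    config: SessionConfig
    truth: GroundTruth
    trials: list
    trace: OcularTrace
    first_sentence_onset_ms: float
    participant: str = "p000"
    filler_items: list = field(default_factory=list)


def _draw_blinks(rng, config: SessionConfig, word_onset: float) -> list[tuple[float, float]]:
    n = rng.poisson(config.blink_rate)
    out = []
    for _ in range(n):
        start = rng.uniform(word_onset - 300.0, word_onset + 1800.0)
        if rng.random() < config.blink_long_frac:
            dur = rng.lognormal(math.log(420.0), 0.25)
        else:
            dur = rng.lognormal(math.log(150.0), 0.35)
        out.append((start, dur))
    return out


def simulate_trial_trace(
    trial: TrialRecord,
    truth: GroundTruth,
    config: SessionConfig,
    rng: np.random.Generator,
    layout: AOILayout | None = None,
):
    """Gaze state sequence and pupil trace for one trial's time span.

    Returns ``(x, y, pupil, valid)`` arrays covering
    [sentence_onset, word_onset + TRIAL_TAIL_MS) at the session rate.
    The pupil here is noise-free (baseline * (1 + template/100)); session
    noise and drift are added by :func:`generate_session` so the AR(1)
    process is continuous across trials.
    """
    layout = layout or AOILayout()
    step = 1000.0 / config.rate
    t0 = trial.sentence_onset_ms
    t1 = trial.target_word_onset_ms + TRIAL_TAIL_MS
    n = int(round((t1 - t0) / step))
    t_abs = t0 + step * np.arange(n)
    t_rel = t_abs - trial.target_word_onset_ms

    # --- gaze: Markov dwell process whose marginal occupancy tracks the
    # ground-truth curves exactly.  Switches arrive at rate 1/mean_dwell;
    # the state drawn at a switch at time s follows q(s) = p(s) + p'(s)*tau
    # (clipped, renormalised), which solves dp/dt = (q - p)/tau, so the
    # occupancy probability at every instant equals the generating curve.
    x = np.empty(n)
    y = np.empty(n)
    tau = config.mean_dwell_ms
    span = t1 - t0
    offset_rel = t0 - trial.target_word_onset_ms

    def _draw_state(t_rel: float, initial: bool) -> str:
        probs = truth.fixation_probs(t_rel, trial.condition)
        pvec = np.array([float(probs[s]) for s in ROLE_STATES])
        if not initial:
            h = 1.0
            hi = truth.fixation_probs(t_rel + h, trial.condition)
            lo = truth.fixation_probs(t_rel - h, trial.condition)
            deriv = np.array([(float(hi[s]) - float(lo[s])) / (2 * h)
                              for s in ROLE_STATES])
            pvec = pvec + deriv * tau
        pvec = np.clip(pvec, 0.0, None)
        pvec /= pvec.sum()
        return ROLE_STATES[rng.choice(len(ROLE_STATES), p=pvec)]

    cursor = 0.0
    state = _draw_state(offset_rel, initial=True)
    while cursor < span:
        dwell = rng.exponential(tau)
        cx, cy = layout.centroid(state)
        i0 = int(cursor / step)
        i1 = min(n, int(math.ceil((cursor + dwell) / step)))
        if i1 > i0:
            x[i0:i1] = cx + rng.normal(0.0, config.gaze_jitter_px)
            y[i0:i1] = cy + rng.normal(0.0, config.gaze_jitter_px)
        cursor += dwell
        state = _draw_state(cursor + offset_rel, initial=False)

    # --- pupil: baseline * (1 + template/100), exact generative inverse
    template = truth.erpd_template(t_rel, trial.condition)
    pupil = config.baseline_pupil * (1.0 + template / 100.0)
    valid = np.ones(n, dtype=bool)

    for start, dur in _draw_blinks(rng, config, trial.target_word_onset_ms):
        j0 = max(0, int(round((start - t0) / step)))
        j1 = min(n, j0 + max(1, int(round(dur / step))))
        if j0 < n:
            valid[j0:j1] = False
            pupil[j0:j1] = 0.0
    return x, y, pupil, valid


def generate_session(
    config: SessionConfig,
    truth: GroundTruth | None = None,
    participant: str = "p000",
    layout: AOILayout | None = None,
) -> Session:
    """One full synthetic session, deterministic given ``config.seed``.

    Critical trials are split half/half between the target-matching and
    target-mismatching conditions (13/13 by default) and interleaved at
    random with fillers sampled without replacement from the 40-item filler
    inventory (the default 62-trial session uses 36 of them).
    """
    truth = truth or GroundTruth.preset(config.presentation)
    layout = layout or AOILayout()
    rng = np.random.default_rng(config.seed)
    step = 1000.0 / config.rate

    n_filler = config.n_trials - config.n_critical
    if n_filler > config.n_inventory_fillers:
        raise ValueError("not enough filler items in the inventory")
    half = config.n_critical // 2
    conditions = (["target_matching"] * half
                  + ["target_mismatching"] * (config.n_critical - half)
                  + ["filler"] * n_filler)
    rng.shuffle(conditions)
    # the 62-trial session samples 36 of the 40 inventory fillers
    filler_items = list(rng.choice(config.n_inventory_fillers, size=n_filler,
                                   replace=False))

    trial_span = SENTENCE_LEAD_MS + TRIAL_TAIL_MS
    trials: list[TrialRecord] = []
    segments = []
    cursor = SESSION_LEAD_MS
    first_sentence_onset = cursor
    roles = ("competitor", "distractor_a", "distractor_b")
    for i, cond in enumerate(conditions):
        sentence_onset = cursor
        word_onset = sentence_onset + SENTENCE_LEAD_MS
        correct = bool(rng.random() < config.correct_rate)
        clicked = "target" if correct else roles[rng.integers(len(roles))]
        trial = TrialRecord(i, cond, config.presentation, sentence_onset,
                            word_onset, clicked, correct)
        trials.append(trial)
        segments.append(simulate_trial_trace(trial, truth, config, rng, layout))
        cursor += trial_span

    n_lead = int(round(SESSION_LEAD_MS / step))
    cx, cy = layout.centroid("center")
    lead = (np.full(n_lead, cx), np.full(n_lead, cy),
            np.full(n_lead, config.baseline_pupil), np.ones(n_lead, dtype=bool))
    x, y, pupil, valid = (np.concatenate(cols) for cols in zip(lead, *segments))

    n = len(pupil)
    if config.noise_sd > 0:
        innov = rng.normal(0.0, config.noise_sd * math.sqrt(1 - config.ar_rho**2), n)
        noise = sps.lfilter([1.0], [1.0, -config.ar_rho], innov)
        pupil = pupil + np.where(valid, noise, 0.0)
    if config.drift_sd > 0:
        walk = np.cumsum(rng.normal(0.0, 1.0, n))
        walk -= walk.mean()
        sd = walk.std() or 1.0
        pupil = pupil + np.where(valid, config.drift_sd * walk / sd, 0.0)
    pupil = np.clip(pupil, 0.0, None)
    pupil[~valid] = 0.0

    t = step * np.arange(n)
    trace = OcularTrace(t, x, y, pupil, valid, config.rate)
    return Session(config, truth, trials, trace, first_sentence_onset, participant,
                   filler_items)


# ---------------------------------------------------------------------------
# end-to-end ground-truth recovery
# ---------------------------------------------------------------------------

def _boxcar(v: np.ndarray, half_width: int) -> np.ndarray:
    k = 2 * half_width + 1
    kernel = np.ones(k) / k
    padded = np.concatenate([np.full(half_width, v[0]), v, np.full(half_width, v[-1])])
    return np.convolve(padded, kernel, mode="valid")


def _align_shift(ref: np.ndarray, shifted: np.ndarray, max_lag: int) -> int:
    """Lag (in samples) minimising the SSE between ``shifted`` and ``ref``.

    The ground truth makes the target-mismatching curves an exactly rigid
    time shift of the target-matching ones, so least-squares alignment of
    the target-competitor difference curves recovers the condition's
    crossover offset using the whole curve rather than a single crossing.
    """
    best, best_sse = 0, np.inf
    for k in range(-max_lag // 4, max_lag + 1):
        if k >= 0:
            a, b = shifted[k:], ref[: len(ref) - k]
        else:
            a, b = shifted[:k], ref[-k:]
        sse = float(np.mean((a - b) ** 2))
        if sse < best_sse:
            best, best_sse = k, sse
    return best


def end_to_end_check(
    preset: str = "NS",
    n_sessions: int = 500,
    seed: int = 0,
    config: SessionConfig | None = None,
    smooth_half_ms: float = 100.0,
    window=ANALYSIS_WINDOW_MS,
) -> dict:
    """Simulate many sessions and recover the generated crossover offset.

    Runs the full chain simulate -> trial screening/blink repair -> epoching
    -> AOI labelling -> pooled proportion curves -> crossover detection, and
    reports the recovered target/competitor crossover per condition and the
    condition offset, next to the generating truth.  Sessions are
    critical-trials-only by default (the fillers carry no crossover
    information), which concentrates the trial budget on the estimate.
    """
    base = config or SessionConfig(n_trials=26, n_critical=26, presentation=preset)
    truth = GroundTruth.preset(preset)
    layout = AOILayout()
    step = 1000.0 / base.rate
    t_epoch = None
    counts: dict[str, dict[str, np.ndarray]] = {}
    n_kept: dict[str, int] = {}
    n_screened = 0
    n_total = 0
    rng = np.random.default_rng(seed)
    for s in range(n_sessions):
        cfg = replace(base, seed=int(rng.integers(2**31 - 1)))
        sess = generate_session(cfg, truth, participant=f"p{s:04d}", layout=layout)
        for trial in sess.trials:
            if trial.condition == "filler":
                continue
            n_total += 1
            result = screen_trial(trial, sess.trace)
            if not result.keep:
                n_screened += 1
                continue
            ep = epoch(result.trace, trial, window, participant=sess.participant)
            labels = label_epoch(ep, layout)
            if t_epoch is None:
                t_epoch = ep.time_ms
            cell = counts.setdefault(
                trial.condition,
                {"target": np.zeros(len(ep)), "competitor": np.zeros(len(ep))})
            cell["target"] += labels == "target"
            cell["competitor"] += labels == "competitor"
            n_kept[trial.condition] = n_kept.get(trial.condition, 0) + 1

    half_w = int(round(smooth_half_ms / step))
    crossovers, truth_crossovers, diffs = {}, {}, {}
    # read the crossover as the point after which the target stays ahead for
    # the rest of the window: robust to noise blips on shallow curves
    persistence = window[1] - window[0]
    for cond, cell in counts.items():
        tgt = _boxcar(cell["target"] / n_kept[cond], half_w)
        cmp_ = _boxcar(cell["competitor"] / n_kept[cond], half_w)
        crossovers[cond] = crossover_time(t_epoch, tgt, cmp_, persistence)
        truth_crossovers[cond] = truth.true_crossover(cond, window)
        diffs[cond] = tgt - cmp_
    cross_diff = offset = None
    if crossovers.get("target_matching") and crossovers.get("target_mismatching"):
        cross_diff = crossovers["target_mismatching"] - crossovers["target_matching"]
    if "target_matching" in diffs and "target_mismatching" in diffs:
        offset = step * _align_shift(diffs["target_matching"],
                                     diffs["target_mismatching"],
                                     max_lag=int(round(400.0 / step)))
    return {
        "preset": preset,
        "n_sessions": n_sessions,
        "n_trials": n_total,
        "n_excluded": n_screened,
        "crossover_ms": crossovers,
        "truth_crossover_ms": truth_crossovers,
        "crossover_difference_ms": cross_diff,
        "recovered_offset_ms": offset,
        "truth_offset_ms": truth.crossover_offset_ms,
    }
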