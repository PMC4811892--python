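"""Pipeline orchestration: one config, one reproducible run directory.

Stages run in dependency order (simulate -> preprocess -> fixations -> erpd
-> gca); every tabular output is written as TSV into the run directory
together with the resolved config, its hash and the root seed, so a re-run
of the same config is byte-identical.  No stage mutates its inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fixation import AOILayout, crossover_time, curves_to_tidy, label_epoch, proportion_curves
from .gca import GCASpec, fit_gca, sequential_comparison
from .ocular import (
    ANALYSIS_WINDOW_MS,
    FIXATION_GCA_WINDOW_MS,
    compute_baseline,
    epoch,
    erpd,
    screen_participant,
    screen_trial,
    write_trace_tsv,
    write_trials_tsv,
)
from .simulate import GroundTruth, Session, SessionConfig, generate_session

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "preprocess", "fixations", "erpd", "gca")


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "runs/run0"
    seed: int = 0
    n_sessions: int = 8
    presentation: str = "NS"
    stages: tuple = STAGES
    session: dict = field(default_factory=dict)  # SessionConfig overrides
    baseline_kinds: tuple = (1, 2)
    write_traces: bool = False
    gca_time_bin_ms: float = 40.0  # thin the grid for the mixed models

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "baseline_kinds" in raw:
            raw["baseline_kinds"] = tuple(raw["baseline_kinds"])
        return cls(**raw)


def _simulate(cfg: RunConfig, out: Path, log: dict):
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth.preset(cfg.presentation)
    sessions = []
    for i in range(cfg.n_sessions):
        scfg = SessionConfig(presentation=cfg.presentation,
                             seed=int(rng.integers(2**31 - 1)),
                             **cfg.session)
        sessions.append(generate_session(scfg, truth, participant=f"p{i:03d}"))
    truth.to_yaml(out / "ground_truth.yaml")
    if cfg.write_traces:
        for s in sessions:
            write_trace_tsv(out / f"trace_{s.participant}.tsv", s.trace)
            write_trials_tsv(out / f"trials_{s.participant}.tsv", s.trials)
    log["n_sessions"] = len(sessions)
    return sessions, truth


def _preprocess(cfg: RunConfig, sessions, out: Path, log: dict):
    layout = AOILayout()
    kept = []
    excl_counts: dict[str, int] = {}
    for s in sessions:
        results = [screen_trial(tr, s.trace) for tr in s.trials]
        for r in results:
            if not r.keep:
                excl_counts[r.reason] = excl_counts.get(r.reason, 0) + 1
        if not screen_participant(results):
            excl_counts["participant_50pct"] = excl_counts.get("participant_50pct", 0) + 1
            continue
        for trial, r in zip(s.trials, results):
            if r.keep:
                kept.append((s, trial, r.trace))
    log["exclusions"] = excl_counts
    log["n_trials_kept"] = len(kept)
    return kept, layout


def _fixation_stage(cfg: RunConfig, kept, layout, out: Path, log: dict):
    epochs, labels = [], []
    for s, trial, trace in kept:
        ep = epoch(trace, trial, ANALYSIS_WINDOW_MS, participant=s.participant)
        epochs.append(ep)
        labels.append(label_epoch(ep, layout))
    curves = proportion_curves(epochs, labels)
    curves_to_tidy(curves).to_csv(out / "fixation_curves.tsv", sep="\t", index=False,
                                  float_format="%.6f")
    rows = []
    for (cond, pres), c in curves.items():
        t = crossover_time(c.time_ms, c.role("target"), c.role("competitor"))
        rows.append({"condition": cond, "presentation": pres,
                     "crossover_ms": np.nan if t is None else t})
    pd.DataFrame(rows).to_csv(out / "crossover.tsv", sep="\t", index=False)
    log["n_epochs"] = len(epochs)
    return epochs, labels


def _erpd_stage(cfg: RunConfig, kept, out: Path, log: dict):
    """%ERPD per trial under each baseline, aggregated to tidy curves."""
    rows = []
    base2 = {}
    for s, trial, trace in kept:
        if 2 in cfg.baseline_kinds and s.participant not in base2:
            base2[s.participant] = compute_baseline(
                trace, kind=2, first_sentence_onset_ms=s.first_sentence_onset_ms)
        ep = epoch(trace, trial, ANALYSIS_WINDOW_MS, participant=s.participant)
        for kind in cfg.baseline_kinds:
            b = (compute_baseline(trace, trial, kind=1) if kind == 1
                 else base2[s.participant])
            rows.append(pd.DataFrame({
                "participant": s.participant,
                "trial_id": trial.trial_id,
                "condition": trial.condition,
                "presentation": trial.presentation,
                "baseline_kind": kind,
                "time_ms": ep.time_ms,
                "erpd_pct": erpd(ep.pupil, b),
            }))
    df = pd.concat(rows, ignore_index=True)
    curves = (df.groupby(["baseline_kind", "condition", "presentation", "time_ms"])
              ["erpd_pct"].mean().reset_index())
    curves.to_csv(out / "erpd_curves.tsv", sep="\t", index=False, float_format="%.4f")
    log["n_erpd_trials"] = df["trial_id"].nunique()
    return df


def _gca_stage(cfg: RunConfig, erpd_df, epochs, labels, out: Path, log: dict):
    bin_ms = cfg.gca_time_bin_ms
    # fixation response: competitor-fixation counts per participant x time bin
    rows = []
    for ep, lab in zip(epochs, labels):
        m = (ep.time_ms >= FIXATION_GCA_WINDOW_MS[0]) & (ep.time_ms < FIXATION_GCA_WINDOW_MS[1])
        rows.append(pd.DataFrame({
            "participant": ep.participant,
            "condition": ep.condition,
            "time_ms": (ep.time_ms[m] // bin_ms) * bin_ms,
            "hit": (lab[m] == "competitor").astype(float),
        }))
    fix = pd.concat(rows, ignore_index=True)
    fix = (fix.groupby(["participant", "condition", "time_ms"])
           .agg(y=("hit", "mean"), n=("hit", "size")).reset_index())
    spec = GCASpec(response="fixation", binary_mode="empirical_logit",
                   factors=("condition",))
    ladder = sequential_comparison(fix, spec)
    ladder.to_csv(out / "gca_fixation_ladder.tsv", sep="\t", index=False)

    e1 = erpd_df[erpd_df["baseline_kind"] == 1]
    agg = (e1.assign(time_ms=(e1["time_ms"] // bin_ms) * bin_ms)
           .groupby(["participant", "condition", "time_ms"])["erpd_pct"]
           .mean().reset_index().rename(columns={"erpd_pct": "y"}))
    espec = GCASpec(response="erpd", factors=("condition",))
    eladder = sequential_comparison(agg, espec)
    eladder.to_csv(out / "gca_erpd_ladder.tsv", sep="\t", index=False)
    # full-model estimate tables (Factor / Estimate / Standard error / Significance)
    fit_gca(fix, spec).table().to_csv(out / "gca_fixation_model.tsv", sep="\t",
                                      index=False, float_format="%.6g")
    fit_gca(agg, espec).table().to_csv(out / "gca_erpd_model.tsv", sep="\t",
                                       index=False, float_format="%.6g")
    log["gca_blocks"] = {"fixation": len(ladder), "erpd": len(eladder)}
    return ladder, eladder


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the selected stages; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                 "version": __version__}
    cfg.to_yaml(out / "config.yaml")

    unknown = set(cfg.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    sessions = truth = None
    if "simulate" in cfg.stages:
        sessions, truth = _simulate(cfg, out, log)
    kept = layout = None
    if "preprocess" in cfg.stages:
        if sessions is None:
            raise RuntimeError("preprocess needs the simulate stage's sessions")
        kept, layout = _preprocess(cfg, sessions, out, log)
    epochs = labels = None
    if "fixations" in cfg.stages:
        if kept is None:
            raise RuntimeError("fixations needs the preprocess stage")
        epochs, labels = _fixation_stage(cfg, kept, layout, out, log)
    erpd_df = None
    if "erpd" in cfg.stages:
        if kept is None:
            raise RuntimeError("erpd needs the preprocess stage")
        erpd_df = _erpd_stage(cfg, kept, out, log)
    if "gca" in cfg.stages:
        if erpd_df is None or epochs is None:
            raise RuntimeError("gca needs the fixations and erpd stages")
        _gca_stage(cfg, erpd_df, epochs, labels, out, log)

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return out
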