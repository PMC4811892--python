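"""Visual-world fixation analysis on the 3x3 display grid.

The display divides the screen into three horizontal and three vertical
bands; the four pictures (target, competitor, two distractors) sit centred
in the four corner quadrants and a cross occupies the centre quadrant.  Gaze
samples are mapped to the quadrant they fall in (pictures are treated as
their whole quadrant), proportion-of-fixation time curves are averaged over
trials with 95% confidence intervals across participants, and the
target/competitor crossover time - the moment the target on average wins
lexical competition - is read off the curves.

:func:`smooth_curve` is the display smoother (locally weighted regression,
span 0.5); it is for plotting only and never feeds statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .ocular import Epoch

__all__ = [
    "AOILayout",
    "FixationCurve",
    "assign_aoi",
    "label_epoch",
    "proportion_curves",
    "crossover_time",
    "smooth_curve",
]

ROLES = ("target", "competitor", "distractor_a", "distractor_b")
CORNERS = ("top_left", "top_right", "bottom_left", "bottom_right")


@dataclass(frozen=True)
class AOILayout:
    """3x3 screen partition with the four picture roles in the corners."""

    screen_w: int = 1024
    screen_h: int = 768
    role_map: dict = field(
        default_factory=lambda: {
            "target": "top_left",
            "competitor": "top_right",
            "distractor_a": "bottom_left",
            "distractor_b": "bottom_right",
        }
    )

    def __post_init__(self) -> None:
        if self.screen_w <= 0 or self.screen_h <= 0:
            raise ValueError("screen dimensions must be positive")
        if sorted(self.role_map) != sorted(ROLES):
            raise ValueError(f"role_map must assign exactly the roles {ROLES}")
        corners = set(self.role_map.values())
        if len(corners) != 4 or not corners <= set(CORNERS):
            raise ValueError("roles must occupy four distinct corner quadrants")

    def corner_of(self, role: str) -> str:
        return self.role_map[role]

    def centroid(self, region: str) -> tuple[float, float]:
        """Pixel centre of a corner quadrant or of the centre cell."""
        w3, h3 = self.screen_w / 3.0, self.screen_h / 3.0
        if region == "center":
            return (1.5 * w3, 1.5 * h3)
        corner = self.role_map.get(region, region)
        row = 0 if corner.startswith("top") else 2
        col = 0 if corner.endswith("left") else 2
        return ((col + 0.5) * w3, (row + 0.5) * h3)


def assign_aoi(x: float, y: float, layout: AOILayout) -> str | None:
    """Map one gaze point to a picture role, 'center', or None (no AOI).

    Grid cells are half-open pixel intervals; the middle cell is the fixation
    cross, edge cells carry no picture, off-screen points map to None.
    """
    if not (0 <= x < layout.screen_w and 0 <= y < layout.screen_h):
        return None
    col = int(x // (layout.screen_w / 3.0))
    row = int(y // (layout.screen_h / 3.0))
    col, row = min(col, 2), min(row, 2)
    if (row, col) == (1, 1):
        return "center"
    corner = {
        (0, 0): "top_left", (0, 2): "top_right",
        (2, 0): "bottom_left", (2, 2): "bottom_right",
    }.get((row, col))
    if corner is None:
        return None
    for role, c in layout.role_map.items():
        if c == corner:
            return role
    return None


_CORNER_BY_CELL = {
    (0, 0): "top_left", (0, 2): "top_right",
    (2, 0): "bottom_left", (2, 2): "bottom_right",
}


def assign_aoi_array(x, y, layout: AOILayout) -> np.ndarray:
    """Vectorised :func:`assign_aoi` over sample arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    on = (x >= 0) & (x < layout.screen_w) & (y >= 0) & (y < layout.screen_h)
    col = np.clip((x // (layout.screen_w / 3.0)).astype(int), 0, 2)
    row = np.clip((y // (layout.screen_h / 3.0)).astype(int), 0, 2)
    out = np.full(len(x), None, dtype=object)
    out[on & (row == 1) & (col == 1)] = "center"
    role_by_corner = {c: r for r, c in layout.role_map.items()}
    for (r, c), corner in _CORNER_BY_CELL.items():
        out[on & (row == r) & (col == c)] = role_by_corner[corner]
    return out


def label_epoch(ep: Epoch, layout: AOILayout) -> np.ndarray:
    """Per-sample AOI labels for an epoch (object array of role/center/None)."""
    labels = assign_aoi_array(ep.x, ep.y, layout)
    labels[~ep.valid] = None
    return labels


@dataclass(frozen=True)
class FixationCurve:
    """Proportion-of-fixation time course for one condition cell."""

    time_ms: np.ndarray
    proportions: pd.DataFrame  # columns = roles, rows = time points
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    n_trials: int
    n_participants: int
    condition: str = ""
    presentation: str = ""

    def role(self, role: str) -> np.ndarray:
        return self.proportions[role].to_numpy()


def _participant_means(labels: np.ndarray, participants: np.ndarray, role: str):
    ind = (labels == role).astype(float)
    by_p = {}
    for p in np.unique(participants):
        by_p[p] = ind[participants == p].mean(axis=0)
    return np.vstack(list(by_p.values()))


def proportion_curves(
    epochs: list[Epoch],
    labels: list[np.ndarray],
    roles: tuple = ROLES,
    ci_method: str = "normal",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Fixation-proportion curves per condition x presentation cell.

    For each time sample the proportion of trials whose gaze is in each
    role's quadrant, with 95% confidence intervals computed across
    participant mean curves (normal approximation by default; set
    ``ci_method='bootstrap'`` to resample participants instead).
    """
    if not epochs:
        raise ValueError("no epochs supplied")
    if ci_method not in ("normal", "bootstrap"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    cells: dict[tuple, list[int]] = {}
    for i, ep in enumerate(epochs):
        cells.setdefault((ep.condition, ep.presentation), []).append(i)
    out = {}
    rng = np.random.default_rng(seed)
    for (cond, pres), idx in cells.items():
        time_ms = epochs[idx[0]].time_ms
        lab = np.vstack([labels[i] for i in idx])
        participants = np.array([epochs[i].participant for i in idx])
        props, lo, hi = {}, {}, {}
        for role in roles:
            ind = (lab == role).astype(float)
            props[role] = ind.mean(axis=0)
            pm = _participant_means(lab, participants, role)
            n_p = pm.shape[0]
            if ci_method == "normal":
                se = pm.std(axis=0, ddof=1) / np.sqrt(n_p) if n_p > 1 else np.zeros(len(time_ms))
                lo[role] = pm.mean(axis=0) - 1.96 * se
                hi[role] = pm.mean(axis=0) + 1.96 * se
            else:
                draws = pm[rng.integers(0, n_p, size=(n_boot, n_p))].mean(axis=1)
                lo[role] = np.quantile(draws, 0.025, axis=0)
                hi[role] = np.quantile(draws, 0.975, axis=0)
        out[(cond, pres)] = FixationCurve(
            time_ms=time_ms,
            proportions=pd.DataFrame(props, index=time_ms),
            ci_low=pd.DataFrame(lo, index=time_ms),
            ci_high=pd.DataFrame(hi, index=time_ms),
            n_trials=len(idx),
            n_participants=len(np.unique(participants)),
            condition=cond,
            presentation=pres,
        )
    return out


def crossover_time(
    time_ms: np.ndarray,
    target: np.ndarray,
    competitor: np.ndarray,
    persistence_ms: float = 100.0,
) -> float | None:
    """First time the target curve rises above the competitor and stays there.

    Returns the earliest time t with target(t) > competitor(t) and
    target >= competitor throughout [t, t + persistence_ms]; None if the
    target never strictly exceeds the competitor that persistently (e.g.
    identical curves).
    """
    time_ms = np.asarray(time_ms, dtype=float)
    diff = np.asarray(target, dtype=float) - np.asarray(competitor, dtype=float)
    if len(diff) < 2:
        raise ValueError("curves too short")
    step = float(np.median(np.diff(time_ms)))
    w = max(1, int(round(persistence_ms / step)))
    nonneg = diff >= 0
    for i in np.nonzero(diff > 0)[0]:
        j = min(len(diff), i + w + 1)
        if nonneg[i:j].all():
            return float(time_ms[i])
    return None


def smooth_curve(time_ms, values, span: float = 0.5) -> np.ndarray:
    """Locally weighted linear regression (tricube weights) for display.

    ``span`` is the fraction of points in each local fit.  Constant and
    linear inputs are reproduced (to numerical tolerance); this smoother is
    used for figures only and never feeds the statistical models.
    """
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    time_ms = np.asarray(time_ms, dtype=float)
    values = np.asarray(values, dtype=float)
    sm = lowess(values, time_ms, frac=span, it=0, return_sorted=False)
    return np.asarray(sm, dtype=float)


def curves_to_tidy(curves: dict) -> pd.DataFrame:
    """Flatten a curve dict to tidy TSV-ready rows."""
    rows = []
    for (cond, pres), c in curves.items():
        for role in c.proportions.columns:
            rows.append(pd.DataFrame({
                "time_ms": c.time_ms,
                "role": role,
                "proportion": c.proportions[role].to_numpy(),
                "ci_low": c.ci_low[role].to_numpy(),
                "ci_high": c.ci_high[role].to_numpy(),
                "condition": cond,
                "presentation": pres,
            }))
    return pd.concat(rows, ignore_index=True)
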